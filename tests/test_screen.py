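import numpy as np
import pandas as pd
import pytest

import oracles
from promoterlab.families import MutantFamily
from promoterlab.pwm import SiteHit
from promoterlab.screen import (
    association_scan,
    classify_sites,
    mwu_pvalue,
    proto_site_census,
    relative_position,
    site_presence_groups,
)
from promoterlab.simstudies import PLANTED_PROTO_WINDOW
from promoterlab.synth import DEFAULT_ACTIVATOR_CONSENSUS, profile_pwm


def test_mwu_exact_matches_full_enumeration():
    rng = np.random.default_rng(5)
    x = rng.normal(size=6)
    y = rng.normal(0.8, size=7)
    assert mwu_pvalue(x, y) == pytest.approx(
        oracles.mwu_exact_by_enumeration(x, y), abs=1e-12
    )


def test_mwu_exact_matches_distribution_up_to_12_12():
    rng = np.random.default_rng(6)
    for m, n in [(3, 3), (5, 9), (12, 12), (4, 12)]:
        x = rng.normal(size=m)
        y = rng.normal(0.5, size=n)
        assert mwu_pvalue(x, y) == pytest.approx(
            oracles.mwu_exact_two_sided(x, y), abs=1e-12
        )


def _sigma():
    return profile_pwm(
        DEFAULT_ACTIVATOR_CONSENSUS["sigma_composite"], "sigma_composite",
        "sigma",
    )


def _planted_gain_family():
    """Parent with a proto-site; 20 daughters gain the site, 30 do not."""
    sigma = _sigma()
    parent = "C" * 40 + PLANTED_PROTO_WINDOW + "C" * 40
    window_start = 41
    gained = parent[:40] + sigma.consensus + parent[40 + sigma.length:]
    rng = np.random.default_rng(8)
    daughters, fluor = [], []
    for _ in range(20):
        daughters.append(gained)
        fluor.append(4.0 + rng.normal(0, 1e-6))
    for k in range(30):
        pos = 5 + k  # mutate far from the planted window for k < 30
        mutant = parent[:pos] + "A" + parent[pos + 1:]
        daughters.append(mutant)
        fluor.append(1.0 + rng.normal(0, 1e-6))
    fam = MutantFamily(
        "gain", parent, daughters, {"GFP": np.array(fluor)}
    )
    return fam, sigma, window_start


def test_site_presence_groups_counts():
    fam, sigma, start = _planted_gain_family()
    pos, neg = site_presence_groups(fam, sigma, start, "top", "GFP")
    assert (len(pos), len(neg)) == (20, 30)
    assert pos.min() > 3.9 and neg.max() < 1.1


def test_association_scan_calls_planted_gain():
    fam, sigma, start = _planted_gain_family()
    calls = association_scan([fam], [sigma], channels=("GFP",))
    gains = calls[calls["direction"] == "gain_activating"]
    assert start in set(gains["window_start"])
    hit = gains[gains["window_start"] == start].iloc[0]
    assert hit["strand"] == "top" and hit["channel"] == "GFP"
    assert hit["n_pos"] == 20 and hit["n_neg"] == 30
    assert hit["delta"] == pytest.approx(3.0, abs=1e-3)
    assert not hit["parent_has_site"]
    # q-values are a single BH family over every tested window
    tested = calls[calls["p_value"].notna()]
    np.testing.assert_allclose(
        tested["q_value"].to_numpy(),
        oracles.bh_qvalues(tested["p_value"].to_numpy()),
        atol=1e-12,
    )
    # one spot-check of the reported p-value against the oracle MWU
    row = tested.iloc[0]
    pos, neg = site_presence_groups(
        fam, sigma, int(row["window_start"]), row["strand"], row["channel"]
    )
    assert row["p_value"] == pytest.approx(mwu_pvalue(pos, neg), abs=1e-15)


def test_min_group_rule_and_include_untested():
    fam, sigma, _ = _planted_gain_family()
    strict = association_scan(
        [fam], [sigma], channels=("GFP",), min_group=25
    )
    # positives number 20 <= 25 at every window, so nothing is testable
    assert strict.empty or strict["p_value"].isna().all()
    full = association_scan(
        [fam], [sigma], channels=("GFP",), include_untested=True
    )
    n_windows = len(fam.parent_sequence) - sigma.length + 1
    assert len(full) == 2 * n_windows  # both strands, one channel


def _call_row(**overrides):
    base = {
        "parent_id": "p", "factor_id": "f", "factor_class": "tf",
        "window_start": 10, "strand": "top", "channel": "GFP",
        "n_pos": 20, "n_neg": 30, "median_pos": 3.0, "median_neg": 1.0,
        "delta": 2.0, "p_value": 1e-6, "q_value": 1e-5,
        "parent_has_site": False,
    }
    base.update(overrides)
    return base


def test_classify_sites_rules():
    rows = [
        _call_row(),  # clean gain
        _call_row(strand="bottom"),  # wrong strand for GFP
        _call_row(strand="bottom", channel="RFP"),  # bottom/RFP matches
        _call_row(delta=0.05),  # below the 0.1 a.u. gain margin
        _call_row(q_value=0.2),  # not significant
        _call_row(parent_has_site=True, median_pos=1.0, median_neg=3.0,
                  delta=-2.0),  # loss of a TF site, derepression
        _call_row(parent_has_site=True, factor_class="sigma",
                  median_pos=1.0, median_neg=3.0, delta=-2.0),  # sigma excluded
        _call_row(parent_has_site=True, median_pos=3.0, median_neg=1.0,
                  delta=2.0),  # losing the site lowers fluor: not repressing
    ]
    out = classify_sites(pd.DataFrame(rows))
    assert list(out["direction"]) == [
        "gain_activating", "none", "gain_activating", "none", "none",
        "loss_repressing", "none", "none",
    ]


def test_proto_site_census():
    sigma = _sigma()
    seq = "C" * 30 + PLANTED_PROTO_WINDOW + "C" * 30
    total, per_factor = proto_site_census(seq, [sigma])
    assert total == 1 and per_factor == {"sigma_composite": 1}
    total, per_factor = proto_site_census("CCC", [sigma])
    assert total == 0  # shorter than the PWM


def test_relative_position_signs():
    hits = [
        SiteHit("sigma", 20, "top", 5.0, "predicted"),
        SiteHit("sigma", 60, "bottom", 5.0, "predicted"),
    ]
    assert relative_position(30, "top", hits) == 10.0
    assert relative_position(12, "top", hits) == -8.0
    # bottom strand reads right-to-left, so downstream flips sign
    assert relative_position(50, "bottom", hits) == 10.0
    assert np.isnan(relative_position(5, "top", [hits[1]]))
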