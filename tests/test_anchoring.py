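"""Hemizygosity anchoring, fuzzy c-means and dose-dilution confirmation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from oatkit import anchoring, simulate
from oatkit.anchoring import (FuzzyKMeans, UNASSIGNED, anchor_groups,
                              call_dose_affected, detect_hemizygous,
                              dilution_anchor, fuzzy_kmeans)
from oatkit.formats import GenotypeMatrix, LinkageMap


def _map21(n_markers=12):
    groups = [f"{i}{g}" for g, ids in
              (("A", [8, 11, 13, 15, 16, 17, 19]),
               ("C", [1, 2, 3, 4, 5, 6, 7]),
               ("D", [9, 10, 12, 14, 18, 20, 21])) for i in ids]
    rows = [{"marker": f"{g}m{i}", "group": g, "position_cm": 5.0 * i}
            for g in groups for i in range(n_markers)]
    return LinkageMap(pd.DataFrame(rows)), groups


# -- hemizygosity detection -------------------------------------------------


def test_detect_hemizygous_rules():
    loci = ["m1", "m2", "m3", "m4"]
    f1 = GenotypeMatrix(pd.DataFrame(
        [["B", "H", "A", "U"]], index=["st1"], columns=loci))
    maternal = pd.Series(["A", "A", "A", "A"], index=loci)
    paternal = pd.Series(["B", "B", "B", "B"], index=loci)
    hemi, anomalies = detect_hemizygous(f1, maternal, paternal)
    assert hemi["st1"] == {"m1"}
    assert anomalies["st1"] == {"m3"}
    assert hemi["st1"].isdisjoint(anomalies["st1"])


def test_detect_hemizygous_excludes_uninformative_loci():
    loci = ["m1", "m2"]
    f1 = GenotypeMatrix(pd.DataFrame(
        [["B", "B"]], index=["st1"], columns=loci))
    maternal = pd.Series(["A", "A"], index=loci)
    paternal = pd.Series(["B", "A"], index=loci)  # m2 uninformative
    hemi, _ = detect_hemizygous(f1, maternal, paternal)
    assert hemi["st1"] == {"m1"}


def test_detect_hemizygous_dimension_mismatch():
    f1 = GenotypeMatrix(pd.DataFrame([["B"]], index=["s"], columns=["m1"]))
    with pytest.raises(ValueError, match="lack"):
        detect_hemizygous(f1, pd.Series(dtype=object), pd.Series(dtype=object))


# -- group anchoring --------------------------------------------------------


def test_anchor_groups_argmax_and_thresholds():
    lmap = LinkageMap(pd.DataFrame(
        [{"marker": f"m{i}", "group": "LG1", "position_cm": float(i)}
         for i in range(13)]))
    stocks = {"st5C": "5C", "st11A": "11A"}
    hemi = {"st5C": {f"m{i}" for i in range(10)},
            "st11A": {f"m{i}" for i in range(10, 13)}}
    report = anchor_groups(hemi, lmap, stocks)
    assert report.assignments["LG1"] == "5C"
    assert report.counts["LG1"] == {"st5C": 10, "st11A": 3}

    assert anchor_groups({}, lmap, stocks).assignments["LG1"] == UNASSIGNED
    tie = {"st5C": {"m0", "m1"}, "st11A": {"m2", "m3"}}
    assert anchor_groups(tie, lmap, stocks).assignments["LG1"] == UNASSIGNED
    single = {"st5C": {"m0"}, "st11A": set()}
    assert anchor_groups(single, lmap, stocks).assignments["LG1"] == UNASSIGNED


def test_anchor_groups_invariant_to_ordering():
    lmap = LinkageMap(pd.DataFrame(
        [{"marker": f"m{i}", "group": "LG1", "position_cm": float(i)}
         for i in range(6)]))
    stocks = {"s1": "1C", "s2": "2C"}
    hemi = {"s1": {"m0", "m1", "m2"}, "s2": {"m3"}}
    a = anchor_groups(hemi, lmap, stocks)
    hemi_r = {"s2": {"m3"}, "s1": {"m2", "m1", "m0"}}
    b = anchor_groups(hemi_r, lmap, dict(reversed(list(stocks.items()))))
    assert a.assignments == b.assignments
    assert a.counts == b.counts


def test_noise_free_panel_recovers_every_group():
    lmap, groups = _map21(n_markers=6)
    stocks = {f"st_{g}": g for g in groups[:15]}
    maternal, paternal, f1, truth = simulate.simulate_monosomic_panel(
        lmap, stocks, noise=0.0, seed=9)
    hemi, anomalies = detect_hemizygous(f1, maternal, paternal)
    report = anchor_groups(hemi, lmap, stocks)
    for stock, chrom in truth.stock_chromosomes.items():
        assert report.assignments[chrom] == chrom
    assert all(not a for a in anomalies.values())


# -- fuzzy c-means ----------------------------------------------------------


def test_fuzzy_kmeans_separated_masses():
    centers, u = fuzzy_kmeans([1, 1, 1, 10, 10, 10], k=2, seed=0)
    assert centers[:, 0] == pytest.approx([1.0, 10.0], abs=1e-6)
    assert u[:3, 0] == pytest.approx(1.0, abs=1e-6)
    assert u[3:, 1] == pytest.approx(1.0, abs=1e-6)


def test_fuzzy_memberships_normalized():
    rng = np.random.default_rng(1)
    values = rng.normal(0, 1, 100)
    _, u = fuzzy_kmeans(values, k=3, seed=2)
    assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)
    assert (u >= 0).all() and (u <= 1).all()


def test_fuzzy_kmeans_degenerate_input():
    with pytest.raises(ValueError, match="distinct"):
        fuzzy_kmeans([5.0, 5.0, 5.0], k=2)


def test_fuzzy_kmeans_recovers_planted_centers():
    df, _ = simulate.simulate_intensities(
        200, ["rep"], {(f"s{i:03d}", "rep") for i in range(100)},
        full_center=1000.0, ratio=0.5, cv=0.1, seed=12)
    centers, _ = fuzzy_kmeans(df["rep"].to_numpy(), k=2, seed=3)
    assert abs(centers[0, 0] - 500.0) / 500.0 < 0.05
    assert abs(centers[1, 0] - 1000.0) / 1000.0 < 0.05


def test_fuzzy_kmeans_sklearn_protocol():
    est = FuzzyKMeans(n_clusters=2, random_state=0)
    params = est.get_params()
    assert params["n_clusters"] == 2 and params["m"] == 2.0
    x = np.array([0.0, 0.1, 5.0, 5.1])
    fitted = clone(est).fit(x)
    assert fitted.cluster_centers_.shape == (2, 1)
    assert sorted(np.unique(fitted.labels_)) == [0, 1]
    assert (fitted.predict([0.05, 5.05]) == fitted.predict([0.05, 5.05])).all()


# -- dose calling -----------------------------------------------------------


def test_dose_calls_nothing_on_uniform_intensities():
    df, _ = simulate.simulate_intensities(20, ["r1", "r2"], set(),
                                          cv=0.1, seed=5)
    report = call_dose_affected(df, {s: "bg" for s in df.index})
    assert report.affected == {}
    assert all(reason == "stable_intensity" for *_, reason in report.skipped)


def test_dose_single_sample_skipped_with_warning():
    df = pd.DataFrame({"r": [100.0]}, index=["s0"])
    with pytest.warns(UserWarning, match="too few"):
        report = call_dose_affected(df, {"s0": "bg"})
    assert report.skipped == [("bg", "r", "too_few_samples")]


def test_dose_detects_planted_half_dose():
    reduced = {(f"s{i:03d}", "rep0") for i in range(5)}
    df, truth = simulate.simulate_intensities(
        20, ["rep0", "rep1"], reduced, ratio=0.5, cv=0.1, seed=6)
    report = call_dose_affected(df, {s: "bg" for s in df.index})
    called = report.affected.get(("bg", "rep0"), set())
    assert called == {s for s, _ in reduced}
    assert ("bg", "rep1") not in report.affected


# -- dilution anchoring -----------------------------------------------------


def test_dilution_anchor_votes_and_ties():
    stocks = {"stX": "3C", "stY": "10D"}
    marker_groups = {f"d{i}": "G1" for i in range(5)}
    calls = {f"d{i}": {"stX"} for i in range(5)}
    report = dilution_anchor(calls, stocks, marker_groups)
    assert report.assignments["G1"] == "3C"

    tied = {f"d{i}": {"stX"} for i in range(3)}
    tied.update({f"e{i}": {"stY"} for i in range(3)})
    marker_groups2 = {m: "G1" for m in tied}
    report2 = dilution_anchor(tied, stocks, marker_groups2)
    assert report2.assignments["G1"] == UNASSIGNED
    assert report2.counts["G1"] == {"stX": 3, "stY": 3}


def test_dilution_agrees_with_snp_anchoring_on_joint_truth():
    lmap, groups = _map21(n_markers=4)
    stocks = {f"st_{g}": g for g in groups[:6]}
    maternal, paternal, f1, truth = simulate.simulate_monosomic_panel(
        lmap, stocks, noise=0.0, seed=14)
    hemi, _ = detect_hemizygous(f1, maternal, paternal)
    snp_report = anchor_groups(hemi, lmap, stocks)

    marker_groups = lmap.group_of()
    reduced = {(stock, m) for stock, chrom in truth.stock_chromosomes.items()
               for m, g in marker_groups.items() if g == chrom}
    df, _ = simulate.simulate_intensities(
        len(stocks), list(marker_groups),
        {(f"s{i:03d}", m) for i, stock in enumerate(sorted(stocks))
         for (s, m) in reduced if s == stock},
        ratio=0.5, cv=0.1, seed=15)
    df.index = sorted(stocks)
    dose = call_dose_affected(df, {s: "bg" for s in df.index},
                              variability_cv=0.2)
    dart_report = dilution_anchor(dose, stocks, marker_groups)
    for g in dart_report.assignments:
        if dart_report.assignments[g] != UNASSIGNED:
            assert dart_report.assignments[g] == snp_report.assignments[g]
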