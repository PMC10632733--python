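import numpy as np
import pandas as pd
import pytest

from mranet.preprocessing import (
    PreprocessingError,
    assemble_dataset,
    normalize_blots,
    normalize_luminex,
)


def _luminex_table(values, treatments, replicates, analyte="AKT"):
    return pd.DataFrame({
        "replicate": replicates,
        "treatment": treatments,
        "analyte": analyte,
        "value": values,
    })


def test_luminex_constant_matrix_gives_unit_fold_changes():
    df = _luminex_table([5.0] * 4, ["DMSO", "T1", "T2", "T3"], [1, 1, 1, 1])
    out = normalize_luminex(df)
    np.testing.assert_allclose(out["fold_change"], 1.0)


def test_luminex_two_sample_arithmetic():
    df = _luminex_table([100.0, 200.0], ["DMSO", "T1"], [1, 1])
    out = normalize_luminex(df)
    assert out.loc[out["treatment"] == "T1", "fold_change"].item() == pytest.approx(2.0)


def test_luminex_matches_per_cell_oracle():
    """Randomized 3-replicate table equals an independent two-step recomputation."""
    rng = np.random.default_rng(42)
    rows = []
    for rep in (1, 2, 3):
        for treatment in ["DMSO", "DMSO", "T1", "T2", "T3"]:
            for analyte in ("AKT", "MEK"):
                rows.append({"replicate": rep, "treatment": treatment,
                             "analyte": analyte, "value": rng.uniform(10, 1000)})
    df = pd.DataFrame(rows).reset_index(names="sample_id")
    out = normalize_luminex(df)
    for _, row in out.iterrows():
        block = df[(df.replicate == row.replicate) & (df.analyte == row.analyte)]
        norm = row.value / block.value.mean()
        ctrl = block[block.treatment == "DMSO"]
        ctrl_norm = (ctrl.value / block.value.mean()).mean()
        assert row.fold_change == pytest.approx(norm / ctrl_norm, rel=1e-12)
    # DMSO controls average to 1 per replicate and analyte
    ctrl_means = (out[out.treatment == "DMSO"]
                  .groupby(["replicate", "analyte"])["fold_change"].mean())
    np.testing.assert_allclose(ctrl_means, 1.0)


def test_luminex_invariant_to_replicate_rescaling():
    rng = np.random.default_rng(0)
    df = _luminex_table(rng.uniform(10, 100, 6),
                        ["DMSO", "T1", "T2"] * 2, [1, 1, 1, 2, 2, 2])
    out1 = normalize_luminex(df)
    df2 = df.copy()
    df2.loc[df2.replicate == 1, "value"] *= 7.3
    out2 = normalize_luminex(df2)
    np.testing.assert_allclose(out1["fold_change"], out2["fold_change"])


def test_luminex_errors():
    with pytest.raises(PreprocessingError, match="control"):
        normalize_luminex(_luminex_table([1.0], ["T1"], [1]))
    with pytest.raises(PreprocessingError, match="zero mean"):
        normalize_luminex(_luminex_table([0.0, 0.0], ["DMSO", "T1"], [1, 1]))


def _blot_table(values, tps, treatments, gels, replicates, analyte="ERK"):
    return pd.DataFrame({
        "replicate": replicates, "treatment": treatments, "analyte": analyte,
        "value": values, "gel": gels, "tps": tps,
    })


def test_blots_all_equal_gives_unit():
    df = _blot_table([3.0] * 4, [2.0] * 4, ["DMSO", "T1", "DMSO", "T1"],
                     ["g1", "g1", "g1", "g1"], [1, 1, 2, 2])
    np.testing.assert_allclose(normalize_blots(df)["fold_change"], 1.0)


def test_blots_loading_normalization_invariance():
    """Doubling band and TPS of a lane leaves its value unchanged."""
    df = _blot_table([3.0, 6.0, 3.0], [2.0, 2.0, 2.0], ["DMSO", "T1", "T2"],
                     ["g1"] * 3, [1, 1, 1])
    df2 = df.copy()
    df2.loc[1, ["value", "tps"]] = [12.0, 4.0]
    np.testing.assert_allclose(normalize_blots(df)["fold_change"],
                               normalize_blots(df2)["fold_change"])


def test_blots_match_three_step_oracle():
    rng = np.random.default_rng(7)
    rows = []
    for gel in [f"g{i}" for i in range(7)]:
        for rep in (1, 2, 3):
            for treatment in ("DMSO", "T1", "T2"):
                rows.append({"replicate": rep, "treatment": treatment,
                             "analyte": "ERK", "gel": gel,
                             "value": rng.uniform(1, 50), "tps": rng.uniform(0.5, 2)})
    df = pd.DataFrame(rows)
    out = normalize_blots(df)
    sig = df.value / df.tps
    gel_mean = sig.groupby(df.gel).transform("mean")
    norm = sig / gel_mean
    ctrl_mean = norm[df.treatment == "DMSO"].mean()
    np.testing.assert_allclose(out["fold_change"], norm / ctrl_mean, rtol=1e-12)
    assert out.loc[out.treatment == "DMSO", "fold_change"].mean() == pytest.approx(1.0)


def test_blots_zero_tps_rejected():
    df = _blot_table([1.0, 1.0], [0.0, 1.0], ["DMSO", "T1"], ["g1", "g1"], [1, 1])
    with pytest.raises(PreprocessingError, match="protein stain"):
        normalize_blots(df)


# --------------------------------------------------------------------- #
# assembly

def _full_fc_table(treatments, analytes, replicates=(1, 2, 3)):
    rng = np.random.default_rng(3)
    rows = []
    for t in treatments:
        for a in analytes:
            for r in replicates:
                rows.append({"replicate": r, "treatment": t, "analyte": a,
                             "fold_change": float(rng.uniform(0.5, 2.0))})
    return pd.DataFrame(rows)


def _study_treatments():
    from mranet.scenarios import study_design

    labels = ["DMSO"]
    labels += ["+".join(c) for c in study_design() if c]
    return labels


def test_assemble_study_scale_counts():
    """53 treatments x 7 readouts x 3 replicates = 1,113 values, 371 pairs."""
    treatments = _study_treatments()
    lum = _full_fc_table(treatments, ["AKT", "GSK3", "mTOR", "MEK"])
    blot = _full_fc_table(treatments, ["ERK", "STAT3", "SMAD2"])
    ds = assemble_dataset([lum, blot])
    assert len(ds.conditions) == 54 and len(ds.readouts) == 4 + 3
    treat = ds.values[ds.treatment_indices]
    assert int(np.isfinite(treat).sum()) == 1113
    assert ds.n_observed() == 371


def test_assemble_exclusion_marks_missing_not_zero():
    treatments = _study_treatments()
    lum = _full_fc_table(treatments, ["AKT", "MEK"])
    ds = assemble_dataset(lum, exclusions=[(3, "AKT")])
    j = ds.readouts.index("AKT")
    excluded = ds.values[ds.treatment_indices, j, 2]
    assert np.isnan(excluded).all() and excluded.size == 53


def test_replicate_correlation_diagnostic_reports_concordance():
    """Concordant replicates correlate strongly; the diagnostic never drops data."""
    from mranet.data import replicate_correlations
    from mranet.scenarios import chain_scenario

    sc = chain_scenario()
    ds = sc.datasets(seed=13)["XX"]
    corr = replicate_correlations(ds)
    assert set(corr) == set(ds.readouts)
    for mat in corr.values():
        assert mat.shape == (3, 3)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.nanmin(mat) > 0.5


def test_assemble_conflicting_duplicates_rejected():
    df = _full_fc_table(["DMSO", "T1"], ["AKT"], replicates=(1,))
    dup = pd.concat([df, df.assign(fold_change=df.fold_change * 2)])
    with pytest.raises(PreprocessingError, match="conflicting"):
        assemble_dataset(dup)
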