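"""Seeded end-to-end simulation studies of the pipeline's operating
characteristics.

Each study regenerates its inputs from the synthetic-data module, runs the
relevant stage(s) end to end, and measures a scalar property: assay
precision on a replicated dilution ladder, false-positive behaviour on
null matrices, recovery of planted differential expression, batch-offset
removal, and noiseless quantitation accuracy.  They back both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import de_pipeline as dp
from . import mrm_quant as mq
from . import synthetic_data as sd

PEPTIDE = "GAFQQAAQILR"


def _curve_from_series(
    series: list[sd.ChromatogramSet], weighting: str = "1/x", analysis: str = "a1"
) -> mq.CalibrationCurve:
    nominal, ratios = [], []
    for cs in series:
        if cs.kind != "calibrator":
            continue
        heavy = mq.extract_peak_areas(cs, PEPTIDE, "heavy")
        light = mq.extract_peak_areas(cs, PEPTIDE, "light", window=heavy.window)
        nominal.append(cs.nominal)
        ratios.append(mq.light_heavy_ratio(light, heavy))
    return mq.fit_calibration(nominal, ratios, weighting=weighting, analysis=analysis)


def calibration_precision(
    seed: int,
    n_analyses: int = 5,
    area_cv: float = 0.05,
    cv_limit: float = 15.0,
    re_limit: float = 15.0,
) -> dict:
    """Replicate-ladder precision/accuracy study.

    Simulates the default 11-point 1:2 dilution ladder (constant 50
    fmol/μL heavy spike, triplicate) across ``n_analyses`` analyses with
    multiplicative log-normal peak-area noise, fits a 1/x-weighted
    calibration per analysis through chromatogram integration, pools the
    back-calculated replicates per level, and evaluates the %CV ≤ 15 /
    \\|%RE\\| ≤ 15 acceptance rule.  Returns the validation report, the
    LOD, and the maximum %CV over levels at least 4× the bottom
    calibrator.
    """
    ss = np.random.SeedSequence(seed)
    curves = []
    for i, child in enumerate(ss.spawn(n_analyses)):
        cfg = sd.SimulationConfig(
            seed=int(child.generate_state(1)[0] % 2**31), area_cv=area_cv
        )
        rng = np.random.default_rng(cfg.seed)
        series = sd.simulate_calibration_series(cfg, rng=rng)
        curves.append(_curve_from_series(series, analysis=f"analysis-{i + 1}"))
    report, lod = mq.validate_curve(curves, cv_limit=cv_limit, re_limit=re_limit)
    bottom = report["nominal"].min()
    eligible = report[report["nominal"] >= 4 * bottom]
    return {
        "report": report,
        "lod": lod,
        "eligible": eligible,
        "max_cv_percent": float(eligible["cv_percent"].max()),
        "all_eligible_pass": bool(eligible["passed"].all()),
    }


def noiseless_quant_recovery(seed: int = 11, amount: float = 7.6) -> dict:
    """Construct a noiseless sample at a known concentration and push it
    through calibration, integration, rdotp and back-calculation."""
    cfg = sd.SimulationConfig(seed=seed, area_cv=0.0)
    curve = _curve_from_series(sd.simulate_calibration_series(cfg))
    chrom = sd.simulate_chromatogram(cfg, amount=amount)
    qr = mq.quantify_sample(chrom, curve, peptide=PEPTIDE, lod=0.98)
    return {
        "concentration": qr.concentration,
        "amount_per_protein": qr.amount_per_protein,
        "rdotp": qr.rdotp,
        "verdict": qr.verdict,
        "relative_error": abs(qr.concentration - amount) / amount,
    }


def null_false_positive_rate(
    seed: int, n_runs: int = 50, n_proteins: int = 1000
) -> dict:
    """Fraction of proteins called significant on null matrices.

    Each run simulates the 8-vs-10 design with batch effects but no
    planted differential expression, runs the full pipeline, and records
    the fraction of proteins passing the FDR < 0.05 and FC > 1.5 calls.
    """
    ss = np.random.SeedSequence(seed)
    fractions = []
    for child in ss.spawn(n_runs):
        cfg = sd.SimulationConfig(
            seed=int(child.generate_state(1)[0] % 2**31),
            n_proteins=n_proteins,
            de_fraction=0.0,
        )
        matrix, _truth = sd.simulate_abundance_matrix(cfg)
        res = dp.run_de_pipeline(matrix)
        fractions.append(res.summary["n_significant"] / res.summary["n_proteins"])
    fractions = np.asarray(fractions)
    mc_se = fractions.std(ddof=1) / np.sqrt(n_runs)
    return {
        "fractions": fractions,
        "mean_fraction": float(fractions.mean()),
        "mc_se": float(mc_se),
        "bound": float(0.05 + 2 * mc_se),
    }


def planted_de_performance(seed: int, n_proteins: int = 2000) -> dict:
    """Sensitivity and log2FC bias with 10% planted DE at |log2FC| = 1.5,
    residual σ = 0.3, on the 8-vs-10 design."""
    cfg = sd.SimulationConfig(seed=seed, n_proteins=n_proteins)
    matrix, truth = sd.simulate_abundance_matrix(cfg)
    res = dp.run_de_pipeline(matrix)
    r = res.results
    de = truth.is_de.loc[r.index]
    sig = r["significant"]
    sensitivity = float((sig & de).sum() / de.sum())
    bias = (r.loc[de, "log2fc"] - truth.log2fc.loc[r.index][de]).abs()
    fdp = float((sig & ~de).sum() / max(int(sig.sum()), 1))
    return {
        "sensitivity": sensitivity,
        "median_abs_log2fc_bias": float(bias.median()),
        "false_discovery_proportion": fdp,
        "n_proteins": int(len(r)),
    }


def batch_removal_performance(
    seed: int, delta: float = 1.0, n_proteins: int = 500
) -> dict:
    """Removal of a planted log2 block offset and preservation of the
    planted genotype contrast."""
    rng = np.random.default_rng(seed)
    n = 18
    genotype = np.array(["KO"] * 9 + ["WT"] * 9)
    batch = np.tile([0, 1, 2], 6)
    lfc = np.zeros(n_proteins)
    lfc[: n_proteins // 10] = 1.5
    log2 = rng.normal(20, 1.5, size=(n_proteins, 1)) + rng.normal(
        0, 0.3, size=(n_proteins, n)
    )
    log2 += lfc[:, None] * (genotype == "KO")
    log2 += delta * (batch == 1)
    values = pd.DataFrame(
        2.0**log2,
        index=[f"P{i}" for i in range(n_proteins)],
        columns=[f"S{i}" for i in range(n)],
    )
    samples = pd.DataFrame(
        {
            "genotype": genotype,
            "age": 10.0,
            "sex": "M",
            "run_order": np.arange(1, n + 1),
        },
        index=values.columns,
    )
    matrix = dp.AbundanceMatrix(values, samples)
    corrected = dp.remove_batch_arsyn(matrix, batch=batch)

    def block_gap(m):
        x = np.log2(m.values.to_numpy())
        return x[:, batch == 1].mean() - x[:, batch != 1].mean()

    def est_lfc(m):
        x = np.log2(m.values.to_numpy())
        ko = genotype == "KO"
        return x[:, ko].mean(axis=1) - x[:, ~ko].mean(axis=1)

    de = lfc > 0
    perturb = np.abs(est_lfc(corrected)[de] - est_lfc(matrix)[de])
    return {
        "offset_removed_fraction": float(
            1.0 - abs(block_gap(corrected)) / abs(block_gap(matrix))
        ),
        "max_logfc_perturbation_fraction": float(perturb.max() / 1.5),
    }
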