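"""Synthetic MRM chromatograms, calibration series and abundance matrices.

The generators stand in for instrument acquisition and label-free export:
they produce data with exactly the statistical structure the downstream
analysis assumes, plus the ground truth needed to score it.

* Chromatograms: co-eluting light/heavy Gaussian peaks per transition on a
  uniform time grid, with multiplicative log-normal area noise and an
  additive baseline.
* Calibration series: a 1:2 serial-dilution ladder of light peptide with a
  constant heavy (SILS) spike, in replicate, plus a zero calibrator
  (heavy only) and a blank.
* Abundance matrices: log-normal protein intensities with planted genotype
  log-fold-changes, piecewise-constant run-order batch offsets, optional
  age/sex covariate effects, and intensity-dependent zeros produced by
  left-censoring below a threshold.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .de_pipeline import AbundanceMatrix, assign_batches

DEFAULT_FRAGMENTS = ("y7", "y6", "y3")
DEFAULT_REL_INTENSITIES = (1.0, 0.8, 0.5)


@dataclass
class SimulationConfig:
    """Parameters shared by the simulators; defaults mirror the assay and
    the plasma study design.

    Chromatogram fields
    -------------------
    retention_time : peak apex, minutes (the assay's quantifier elutes
        near 1.2–1.6 min on a 5-minute gradient).
    peak_sigma : Gaussian peak width, minutes.
    amount : light analyte concentration, fmol/μL.
    sils_amount : heavy internal-standard concentration, fmol/μL
        (the assay spikes 50 fmol/μL into every calibrator and sample).
    response_factor : integrated area counts·min per fmol/μL.
    rel_intensities : relative fragment response pattern shared by light
        and heavy channels.
    area_cv : coefficient of variation of the multiplicative log-normal
        noise on each peak area.
    baseline, baseline_noise_sd : additive baseline level and Gaussian
        noise on the trace (clipped at zero).

    Calibration fields
    ------------------
    top_concentration, n_levels : 1:2 serial dilution starting at the top
        concentration (default 1000 fmol/μL = 1 pmol/μL, 11 points).
    replicates : replicates per level (default triplicate).

    Matrix fields
    -------------
    n_proteins, n_ko, n_wt : design size (default 2000 proteins, 8
        knockout vs 10 wild-type, the plasma design).
    de_fraction, de_log2fc : fraction of proteins carrying a genotype
        effect and its log2 magnitude (sign random per protein).
    noise_sd : residual log2 standard deviation.
    baseline_mean, baseline_sd : log2 location/spread of protein baselines.
    n_batches, batch_sd : consecutive run-order blocks and the SD of their
        shared log2 offsets.
    age_effect_sd, sex_effect_sd : SDs of per-protein covariate slopes.
    zero_threshold : linear intensity below which a value is recorded as 0.
    """

    seed: int = 0
    # chromatograms
    retention_time: float = 1.6
    peak_sigma: float = 0.02
    amount: float = 100.0
    sils_amount: float = 50.0
    response_factor: float = 100.0
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    rel_intensities: tuple[float, ...] = DEFAULT_REL_INTENSITIES
    area_cv: float = 0.0
    baseline: float = 5.0
    baseline_noise_sd: float = 0.0
    time_start: float = 0.5
    time_end: float = 2.7
    dt: float = 0.005
    # calibration ladder
    top_concentration: float = 1000.0
    n_levels: int = 11
    replicates: int = 3
    # abundance matrices
    n_proteins: int = 2000
    n_ko: int = 8
    n_wt: int = 10
    de_fraction: float = 0.1
    de_log2fc: float = 1.5
    noise_sd: float = 0.3
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    n_batches: int = 3
    batch_sd: float = 0.2
    age_effect_sd: float = 0.0
    sex_effect_sd: float = 0.0
    zero_threshold: float = 1e5

    def __post_init__(self) -> None:
        if self.peak_sigma <= 0:
            raise ValueError("peak width must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("DE fraction must lie in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.fragments) != len(self.rel_intensities):
            raise ValueError("fragments and rel_intensities must align")


@dataclass
class ChromatogramSet:
    """Per-transition intensity traces on a shared uniform time grid.

    ``traces`` maps ``(peptide, fragment, label)`` channel keys to
    intensity arrays; ``nominal`` carries the known light concentration
    for calibrators (None for study samples), ``kind`` distinguishes
    calibrators from the zero calibrator and the blank.
    """

    times: np.ndarray
    traces: dict[tuple[str, str, str], np.ndarray]
    nominal: float | None = None
    kind: str = "sample"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        for key, tr in self.traces.items():
            tr = np.asarray(tr, dtype=float)
            if tr.shape != self.times.shape:
                raise ValueError(f"trace {key} does not match the time grid")
            if (tr < 0).any():
                raise ValueError(f"negative intensities in trace {key}")
            self.traces[key] = tr

    def channels(self) -> list[tuple[str, str, str]]:
        return list(self.traces)

    # -- long-format text I/O ---------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pep, frag, label), tr in self.traces.items():
            rows.append(
                pd.DataFrame(
                    {
                        "peptide": pep,
                        "fragment": frag,
                        "label": label,
                        "time": self.times,
                        "intensity": tr,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path_or_buf, sep: str = ",") -> None:
        self.to_frame().to_csv(path_or_buf, sep=sep, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "ChromatogramSet":
        traces = {}
        times = None
        for key, grp in frame.groupby(["peptide", "fragment", "label"], sort=False):
            grp = grp.sort_values("time")
            if times is None:
                times = grp["time"].to_numpy()
            traces[tuple(key)] = grp["intensity"].to_numpy()
        return cls(times=times, traces=traces, **kwargs)

    @classmethod
    def from_csv(cls, path_or_buf, sep: str = ",", **kwargs) -> "ChromatogramSet":
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        return cls.from_frame(pd.read_csv(path_or_buf, sep=sep), **kwargs)


def _gaussian(times: np.ndarray, area: float, rt: float, sigma: float) -> np.ndarray:
    amp = area / (sigma * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((times - rt) / sigma) ** 2)


def simulate_chromatogram(
    config: SimulationConfig,
    peptide: str = "GAFQQAAQILR",
    amount: float | None = None,
    rng: np.random.Generator | None = None,
    kind: str = "sample",
    nominal: float | None = None,
) -> ChromatogramSet:
    """One light+heavy chromatogram set for a peptide.

    Each transition trace is a Gaussian peak centred at the peptide's
    retention time (light and heavy co-elute), with area = concentration ×
    response factor × relative fragment intensity, multiplied by unbiased
    log-normal noise of the configured CV, plus baseline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if amount is None:
        amount = config.amount
    times = np.arange(config.time_start, config.time_end, config.dt)
    cv = config.area_cv
    sd = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    traces: dict[tuple[str, str, str], np.ndarray] = {}
    for label, conc in (("light", amount), ("heavy", config.sils_amount)):
        for frag, rel in zip(config.fragments, config.rel_intensities):
            area = conc * config.response_factor * rel
            if sd > 0 and area > 0:
                area *= np.exp(rng.normal(0.0, sd) - 0.5 * sd**2)
            tr = _gaussian(times, area, config.retention_time, config.peak_sigma)
            tr = tr + config.baseline
            if config.baseline_noise_sd > 0:
                tr = tr + rng.normal(0.0, config.baseline_noise_sd, size=tr.shape)
            traces[(peptide, frag, label)] = np.clip(tr, 0.0, None)
    return ChromatogramSet(times=times, traces=traces, kind=kind, nominal=nominal)


def dilution_ladder(top: float, n_levels: int) -> np.ndarray:
    """1:2 serial dilution: ``top, top/2, …`` for ``n_levels`` points."""
    if top <= 0 or n_levels < 1:
        raise ValueError("need a positive top concentration and >= 1 level")
    return top / 2.0 ** np.arange(n_levels)


def simulate_calibration_series(
    config: SimulationConfig,
    peptide: str = "GAFQQAAQILR",
    rng: np.random.Generator | None = None,
) -> list[ChromatogramSet]:
    """A replicated calibration ladder plus zero calibrator and blank.

    Light-peptide levels follow a 1:2 serial dilution from
    ``top_concentration`` over ``n_levels`` points, each with the constant
    heavy SILS spike, in ``replicates`` replicates.  The zero calibrator
    contains only the heavy spike; the blank contains solvent only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    levels = dilution_ladder(config.top_concentration, config.n_levels)
    out = []
    for level in levels:
        for _rep in range(config.replicates):
            out.append(
                simulate_chromatogram(
                    config, peptide, amount=level, rng=rng,
                    kind="calibrator", nominal=float(level),
                )
            )
    out.append(
        simulate_chromatogram(
            config, peptide, amount=0.0, rng=rng, kind="zero", nominal=0.0
        )
    )
    blank_cfg = replace(config, sils_amount=0.0)
    out.append(
        simulate_chromatogram(
            blank_cfg, peptide, amount=0.0, rng=rng, kind="blank", nominal=0.0
        )
    )
    return out


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------


@dataclass
class MatrixTruth:
    """Ground truth accompanying a simulated abundance matrix."""

    is_de: pd.Series
    log2fc: pd.Series
    batch: pd.Series
    batch_offsets: np.ndarray


def _plant_matrix(
    config: SimulationConfig,
    rng: np.random.Generator,
    de_ids: np.ndarray,
    signs: np.ndarray,
    tissue: str | None = None,
) -> tuple[AbundanceMatrix, MatrixTruth]:
    p, n_ko, n_wt = config.n_proteins, config.n_ko, config.n_wt
    n = n_ko + n_wt
    proteins = pd.Index([f"P{i:05d}" for i in range(p)], name="accession")
    sample_ids = [f"KO{i + 1}" for i in range(n_ko)] + [
        f"WT{i + 1}" for i in range(n_wt)
    ]
    genotype = np.array(["KO"] * n_ko + ["WT"] * n_wt)
    run_order = rng.permutation(n) + 1
    batch = assign_batches(run_order, config.n_batches)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    age = rng.integers(8, 15, size=n).astype(float)
    sex = rng.choice(["M", "F"], size=n)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    log2fc = np.zeros(p)
    log2fc[de_ids] = signs * config.de_log2fc
    log2 = baseline[:, None] + np.zeros((p, n))
    log2 += log2fc[:, None] * (genotype == "KO")[None, :]
    log2 += batch_offsets[batch][None, :]
    if config.age_effect_sd > 0:
        slopes = rng.normal(0.0, config.age_effect_sd, size=p)
        log2 += slopes[:, None] * (age - age.mean())[None, :]
    if config.sex_effect_sd > 0:
        slopes = rng.normal(0.0, config.sex_effect_sd, size=p)
        log2 += slopes[:, None] * (sex == "M")[None, :]
    log2 += rng.normal(0.0, config.noise_sd, size=(p, n))
    intensity = 2.0**log2
    intensity[intensity < config.zero_threshold] = 0.0

    samples = pd.DataFrame(
        {
            "genotype": genotype,
            "age": age,
            "sex": sex,
            "run_order": run_order,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    if tissue is not None:
        samples["tissue"] = tissue
    matrix = AbundanceMatrix(
        pd.DataFrame(intensity, index=proteins, columns=samples.index), samples
    )
    truth = MatrixTruth(
        is_de=pd.Series(np.isin(np.arange(p), de_ids), index=proteins),
        log2fc=pd.Series(log2fc, index=proteins),
        batch=pd.Series(batch, index=samples.index),
        batch_offsets=batch_offsets,
    )
    return matrix, truth


def simulate_abundance_matrix(
    config: SimulationConfig, tissue: str | None = None
) -> tuple[AbundanceMatrix, MatrixTruth]:
    """A knockout-vs-WT protein × sample matrix with known ground truth.

    Log-normal intensities; a ``de_fraction`` of proteins carries a
    genotype log2 fold change of magnitude ``de_log2fc`` with random sign;
    run-order batch offsets are shared across proteins within consecutive
    acquisition blocks; intensities below ``zero_threshold`` are recorded
    as zero.
    """
    if config.n_ko < 2 or config.n_wt < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(config.seed)
    n_de = int(round(config.de_fraction * config.n_proteins))
    de_ids = rng.choice(config.n_proteins, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    return _plant_matrix(config, rng, de_ids, signs, tissue=tissue)


def simulate_tissue_panel(
    config: SimulationConfig,
    n_tissues: int = 4,
    shared_fraction: float = 0.2,
    tissue_names: Sequence[str] | None = None,
) -> tuple[list[tuple[AbundanceMatrix, MatrixTruth]], pd.Index]:
    """Per-tissue matrices with a planted cross-tissue shared DE core.

    A ``shared_fraction`` of each tissue's DE quota is drawn from a common
    core set (differential in every tissue); the remainder is
    tissue-specific.  Returns the per-tissue (matrix, truth) pairs and the
    shared core's protein ids.
    """
    if n_tissues < 2:
        raise ValueError("need >= 2 tissues")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if tissue_names is None:
        tissue_names = [f"tissue{i + 1}" for i in range(n_tissues)]
    rng = np.random.default_rng(config.seed)
    n_de = int(round(config.de_fraction * config.n_proteins))
    n_shared = int(round(shared_fraction * n_de))
    pool = rng.permutation(config.n_proteins)
    shared = pool[:n_shared]
    shared_signs = rng.choice([-1.0, 1.0], size=n_shared)
    remaining = pool[n_shared:]
    out = []
    offset = 0
    for t in range(n_tissues):
        specific = remaining[offset : offset + (n_de - n_shared)]
        offset += n_de - n_shared
        if len(specific) < n_de - n_shared:
            raise ValueError("not enough proteins for disjoint tissue-specific DE")
        de_ids = np.concatenate([shared, specific]).astype(int)
        signs = np.concatenate(
            [shared_signs, rng.choice([-1.0, 1.0], size=len(specific))]
        )
        sub_rng = np.random.default_rng([config.seed, 7919, t])
        out.append(
            _plant_matrix(config, sub_rng, de_ids, signs, tissue=tissue_names[t])
        )
    proteins = out[0][0].proteins
    return out, proteins[shared]
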