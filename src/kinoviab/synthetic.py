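"""Synthetic study-condition generator.

Emulates the five inputs of the viability-prediction pipeline with known
ground truth: sparse multi-dose kinome inhibition records, baseline omics
matrices (expression / CNV / proteomics / CRISPR-KO dependency), fitted
four-parameter log-logistic (LL.4) dose-response parameters, a
protein-interaction edge list with planted enrichment, and a kinase
annotation table.

The planted mechanism: each compound has a small set of target proteins
whose relative binding intensity decays logistically with concentration
(shared Hill slope, per-pair potency).  Each compound also has a disjoint
set of driver genes; a cell line's sensitivity to a compound is a logistic
function of its drivers' expression.  True viability is

    V(l, j, x) = 1 - s(l, j) * (1 - min_p I(j, p, x))

over the compound's targets p.  Because the slope is shared, the min is the
single most potent target's curve, so V is exactly an LL.4 curve with upper
asymptote 1, lower asymptote 1 - s, inflection at the best potency, and
slope equal to the shared Hill slope.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .viability import ll4

logger = logging.getLogger(__name__)

#: the eight assay concentrations, in molar (3 nM .. 30 uM)
DEFAULT_DOSE_GRID = (3e-9, 1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6, 3e-5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Counts and rates mirror a scaled-down version of the real resources:
    a kinome-wide inhibition panel, genome-wide expression, a per-compound
    handful of true targets, and rare single-concentration gaps/outliers.
    """

    n_cell_lines: int = 40
    n_compounds: int = 30
    n_proteins: int = 80
    n_genes: int = 200
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    targets_per_compound: int = 3
    n_driver_genes: int = 3
    noise_sd: float = 0.05
    gap_rate: float = 0.02
    outlier_rate: float = 0.001
    growth_fraction: float = 0.02
    hill_slope: float = 1.5
    potency_range: tuple[float, float] = (1e-8, 3e-6)
    sens_gain: float = 0.6
    sens_offset_sd: float = 1.0
    expr_baseline: float = 3.0
    expr_sd: float = 1.0
    driver_effect: float = 1.2
    driver_noise: float = 0.4
    proteomics_missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_compounds", "n_proteins", "n_genes",
                     "targets_per_compound", "n_driver_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        grid = np.asarray(self.dose_grid, dtype=float)
        if grid.size < 2 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("dose_grid must be strictly increasing and positive")
        for name in ("gap_rate", "outlier_rate", "growth_fraction",
                     "proteomics_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gap_rate >= 0.5:
            raise ValueError(
                "gap_rate >= 0.5 would break the isolated-gap premise of "
                "neighbor imputation")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.targets_per_compound > self.n_proteins:
            raise ValueError("targets_per_compound exceeds n_proteins")
        if self.n_driver_genes * self.n_compounds > self.n_genes:
            raise ValueError(
                "driver gene sets are disjoint across compounds: need "
                "n_driver_genes * n_compounds <= n_genes")

    # --- identifier helpers -------------------------------------------------
    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i:03d}" for i in range(self.n_cell_lines)]

    @property
    def compounds(self) -> list[str]:
        return [f"CMPD{i:03d}" for i in range(self.n_compounds)]

    @property
    def proteins(self) -> list[str]:
        return [f"KIN{i:03d}" for i in range(self.n_proteins)]

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Everything needed to verify downstream recovery without re-derivation."""

    target_sets: dict[str, list[str]]
    potencies: dict[str, dict[str, float]]          # compound -> protein -> k (M)
    hill_slope: float
    driver_genes: dict[str, list[str]]
    sensitivity: dict[tuple[str, str], float]       # (cell line, compound) -> s
    true_viability: dict[tuple[str, str, float], float]
    growth_combos: list[tuple[str, str]] = field(default_factory=list)
    outlier_records: list[tuple[str, str, float]] = field(default_factory=list)
    gap_records: list[tuple[str, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        if any(len(t) == 0 for t in self.target_sets.values()):
            raise ValueError("every compound must have at least one target")
        if any(not 0.0 <= s <= 1.0 for s in self.sensitivity.values()):
            raise ValueError("sensitivity must lie in [0, 1]")
        if any(not 0.0 <= v <= 1.2 for v in self.true_viability.values()):
            raise ValueError("true viability must lie in [0, 1.2]")

    def to_json(self, path) -> None:
        payload = {
            "target_sets": self.target_sets,
            "potencies": self.potencies,
            "hill_slope": self.hill_slope,
            "driver_genes": self.driver_genes,
            "sensitivity": [[l, j, s] for (l, j), s in self.sensitivity.items()],
            "true_viability": [[l, j, x, v]
                               for (l, j, x), v in self.true_viability.items()],
            "growth_combos": [list(t) for t in self.growth_combos],
            "outlier_records": [list(t) for t in self.outlier_records],
            "gap_records": [list(t) for t in self.gap_records],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            target_sets=d["target_sets"],
            potencies=d["potencies"],
            hill_slope=d["hill_slope"],
            driver_genes=d["driver_genes"],
            sensitivity={(l, j): s for l, j, s in d["sensitivity"]},
            true_viability={(l, j, x): v for l, j, x, v in d["true_viability"]},
            growth_combos=[tuple(t) for t in d["growth_combos"]],
            outlier_records=[tuple(t) for t in d["outlier_records"]],
            gap_records=[tuple(t) for t in d["gap_records"]],
        )


def _rng(config: SyntheticConfig, salt: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _target_map(config: SyntheticConfig) -> tuple[dict[str, list[str]],
                                                  dict[str, dict[str, float]]]:
    rng = _rng(config, 1)
    lo, hi = config.potency_range
    targets: dict[str, list[str]] = {}
    potencies: dict[str, dict[str, float]] = {}
    for cmpd in config.compounds:
        picked = sorted(rng.choice(config.proteins, size=config.targets_per_compound,
                                   replace=False).tolist())
        targets[cmpd] = picked
        ks = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(picked)))
        potencies[cmpd] = dict(zip(picked, ks.tolist()))
    return targets, potencies


def target_intensity(x: np.ndarray, potency: float, slope: float) -> np.ndarray:
    """Relative intensity of a planted target: 1/(1+exp(slope*(ln x - ln k)))."""
    return 1.0 / (1.0 + np.exp(slope * (np.log(x) - np.log(potency))))


def generate_inhibition_records(config: SyntheticConfig) -> pd.DataFrame:
    """Sparse long-format inhibition records for planted targets only.

    Returns a DataFrame with columns ``compound, protein, concentration,
    relative_intensity``.  A fraction ``gap_rate`` of interior grid values is
    withheld (never two adjacent in one series) and a fraction
    ``outlier_rate`` of intensities is inflated by a factor > 3.
    """
    targets, potencies = _target_map(config)
    rng = _rng(config, 2)
    grid = np.asarray(config.dose_grid)
    rows, gaps, outliers = [], [], []
    for cmpd in config.compounds:
        for prot in targets[cmpd]:
            vals = target_intensity(grid, potencies[cmpd][prot], config.hill_slope)
            missing = np.zeros(grid.size, dtype=bool)
            for i in range(1, grid.size - 1):          # interior cells only
                if missing[i - 1]:
                    continue                           # keep gaps isolated
                if rng.random() < config.gap_rate:
                    missing[i] = True
            for i, x in enumerate(grid):
                if missing[i]:
                    gaps.append((cmpd, prot, float(x)))
                    continue
                v = float(vals[i])
                if rng.random() < config.outlier_rate:
                    v *= float(rng.uniform(3.5, 6.0))
                    outliers.append((cmpd, prot, float(x)))
                rows.append((cmpd, prot, float(x), v))
    df = pd.DataFrame(rows, columns=["compound", "protein", "concentration",
                                     "relative_intensity"])
    df.attrs["gap_records"] = gaps
    df.attrs["outlier_records"] = outliers
    return df


def generate_kinase_annotation(config: SyntheticConfig) -> pd.DataFrame:
    """Per-protein class labels: well-studied (light) or understudied (dark)
    kinases, plus co-purifying non-kinases — roughly half the panel, as in
    kinobead pulldowns."""
    rng = _rng(config, 3)
    classes = rng.choice(["light", "dark", "non-kinase"],
                         p=[0.35, 0.15, 0.5], size=config.n_proteins)
    return pd.DataFrame({"protein": config.proteins, "class": classes})


def generate_omics(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Baseline omics bundle keyed by class name.

    ``expression`` is on the log2(TPM+1) scale (clipped at 0); each
    compound's driver genes load on a shared per-(line, compound) latent
    factor so that driver expression tracks the planted sensitivity.
    ``proteomics`` carries planted missing entries; ``dependency`` has a few
    incomplete cell lines to exercise the completeness filter.
    """
    rng = _rng(config, 4)
    lines, genes = config.cell_lines, config.genes
    targets, _ = _target_map(config)

    latent = rng.normal(size=(config.n_cell_lines, config.n_compounds))
    expr = config.expr_baseline + config.expr_sd * rng.normal(
        size=(config.n_cell_lines, config.n_genes))

    driver_genes: dict[str, list[str]] = {}
    gene_pool = rng.permutation(config.n_genes)
    cursor = 0
    for jc, cmpd in enumerate(config.compounds):
        idx = gene_pool[cursor:cursor + config.n_driver_genes]
        cursor += config.n_driver_genes
        driver_genes[cmpd] = sorted(genes[g] for g in idx)
        for g in idx:
            expr[:, g] = (config.expr_baseline
                          + config.driver_effect * latent[:, jc]
                          + config.driver_noise * rng.normal(size=config.n_cell_lines))
    expr = np.clip(expr, 0.0, None)

    expression = pd.DataFrame(expr, index=lines, columns=genes)
    cnv = pd.DataFrame(2.0 + 0.3 * rng.normal(size=expr.shape),
                       index=lines, columns=genes)
    prot = pd.DataFrame(rng.normal(loc=0.0, scale=1.0, size=expr.shape),
                        index=lines, columns=genes)
    mask = rng.random(expr.shape) < config.proteomics_missing_rate
    prot = prot.mask(mask)
    dep = pd.DataFrame(rng.normal(loc=-0.2, scale=0.4, size=expr.shape),
                       index=lines, columns=genes)
    # a couple of incomplete dependency lines, as in the CRISPR-KO resource
    n_bad = min(2, config.n_cell_lines - 1)
    for i in range(n_bad):
        dep.iloc[i, int(rng.integers(config.n_genes))] = np.nan

    bundle = {"expression": expression, "cnv": cnv,
              "proteomics": prot, "dependency": dep}
    bundle["expression"].attrs["driver_genes"] = driver_genes
    bundle["expression"].attrs["latent"] = latent
    return bundle


def _sensitivity(config: SyntheticConfig, latent: np.ndarray) -> np.ndarray:
    """Logistic sensitivity: a per-compound offset (compounds differ in how
    much killing they produce overall) plus a smaller per-line modulation
    driven by the compound's driver-gene expression.  The offset dominates,
    mirroring screens where compound identity explains most viability
    variance and baseline expression fine-tunes per line."""
    offsets = _rng(config, 7).normal(scale=config.sens_offset_sd,
                                     size=config.n_compounds)
    return 1.0 / (1.0 + np.exp(-(offsets[None, :]
                                 + config.sens_gain * latent)))


def _ll4_for_fit(logx, b, c, d, loge):
    z = np.clip(b * (logx - loge), -50.0, 50.0)
    return c + (d - c) / (1.0 + np.exp(z))


def fit_ll4(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Nonlinear least-squares LL.4 fit on log-concentration.

    Multi-start around (b, c, d, e) = (1, min y, max y, geometric-median
    dose); returns (b, c, d, e).  Raises RuntimeError if no start converges.
    """
    logx = np.log(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    loge0 = float(np.median(logx))
    best, best_sse = None, np.inf
    # an essentially exact fit ends the multi-start early
    tol = 1e-10 * y.size
    starts = [(1.0, loge0), (0.5, loge0), (2.0, loge0),
              (1.0, logx[0] + 0.25 * (logx[-1] - logx[0])),
              (1.0, logx[0] + 0.75 * (logx[-1] - logx[0]))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b0, le0 in starts:
            try:
                popt, _ = curve_fit(
                    _ll4_for_fit, logx, y,
                    p0=[b0, float(y.min()), float(y.max()), le0],
                    maxfev=5000)
            except RuntimeError:
                continue
            sse = float(np.sum((_ll4_for_fit(logx, *popt) - y) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
            if best_sse < tol:
                break
    if best is None:
        raise RuntimeError("LL.4 fit failed to converge from all starts")
    b, c, d, loge = best
    return float(b), float(c), float(d), float(np.exp(loge))


def generate_dose_response(
    config: SyntheticConfig,
    inhibition: pd.DataFrame,
    omics: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, GroundTruth]:
    """LL.4 parameter table plus the ground truth that produced it.

    True viability per (line, compound, dose) follows the planted mechanism;
    LL.4 parameters are refit to the noisy curve (Gaussian noise
    ``noise_sd``).  A fraction ``growth_fraction`` of combos is replaced with
    growth-enhancing parameter sets to exercise the downstream filter.
    """
    targets, potencies = _target_map(config)
    latent = omics["expression"].attrs["latent"]
    driver_genes = omics["expression"].attrs["driver_genes"]
    rng = _rng(config, 5)
    grid = np.asarray(config.dose_grid)
    sens = _sensitivity(config, latent)

    rows = []
    sensitivity: dict[tuple[str, str], float] = {}
    true_v: dict[tuple[str, str, float], float] = {}
    growth_combos: list[tuple[str, str]] = []
    n_failed = 0
    for jc, cmpd in enumerate(config.compounds):
        k_best = min(potencies[cmpd].values())
        inh_min = target_intensity(grid, k_best, config.hill_slope)
        for il, line in enumerate(config.cell_lines):
            s = float(sens[il, jc])
            sensitivity[(line, cmpd)] = s
            v = 1.0 - s * (1.0 - inh_min)
            for x, vx in zip(grid, v):
                true_v[(line, cmpd, float(x))] = float(vx)
            if rng.random() < config.growth_fraction:
                # planted growth-enhancing curve: higher dose, higher signal
                b, c, d, e = 1.0, float(rng.uniform(1.05, 1.2)), \
                    float(rng.uniform(0.85, 0.95)), float(np.exp(np.median(np.log(grid))))
                growth_combos.append((line, cmpd))
                rows.append((line, cmpd, b, c, d, e))
                continue
            y = v + rng.normal(scale=config.noise_sd, size=grid.size) \
                if config.noise_sd > 0 else v
            try:
                b, c, d, e = fit_ll4(grid, y)
            except RuntimeError:
                n_failed += 1
                logger.warning("LL.4 fit failed for (%s, %s); combo dropped",
                               line, cmpd)
                continue
            rows.append((line, cmpd, b, c, d, e))
    if n_failed:
        logger.info("dropped %d combos with failed fits", n_failed)

    params = pd.DataFrame(rows, columns=["cell_line", "compound",
                                         "b", "c", "d", "e"])
    truth = GroundTruth(
        target_sets=targets,
        potencies=potencies,
        hill_slope=config.hill_slope,
        driver_genes=driver_genes,
        sensitivity=sensitivity,
        true_viability=true_v,
        growth_combos=growth_combos,
        outlier_records=list(inhibition.attrs.get("outlier_records", [])),
        gap_records=list(inhibition.attrs.get("gap_records", [])),
    )
    truth.validate()
    return params, truth


def generate_network(
    config: SyntheticConfig,
    enrichment_strength: float = 5.0,
    p0: float = 0.02,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Random interaction edge list with planted driver↔target enrichment.

    Background node pairs get an edge with probability ``p0``; pairs of
    (driver gene, target protein) get one with probability
    ``min(1, p0 * enrichment_strength)``.  Confidence scores are uniform in
    [0.4, 1.0].  Returns a DataFrame (node_a, node_b, confidence).
    """
    if truth is None:
        targets, potencies = _target_map(config)
        omics = generate_omics(config)
        driver_genes = omics["expression"].attrs["driver_genes"]
    else:
        targets = truth.target_sets
        driver_genes = truth.driver_genes
    rng = _rng(config, 6)
    nodes = list(config.genes) + list(config.proteins)
    driver_set = {g for gs in driver_genes.values() for g in gs}
    target_set = {p for ps in targets.values() for p in ps}
    p_boost = min(1.0, p0 * enrichment_strength)

    rows = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            boosted = (a in driver_set and b in target_set) or \
                      (b in driver_set and a in target_set)
            p = p_boost if boosted else p0
            if rng.random() < p:
                rows.append((a, b, float(rng.uniform(0.4, 1.0))))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])


@dataclass
class SyntheticBundle:
    """All generated inputs for one run of the pipeline."""

    config: SyntheticConfig
    inhibition_records: pd.DataFrame
    omics: dict[str, pd.DataFrame]
    dose_response: pd.DataFrame
    truth: GroundTruth
    network: pd.DataFrame
    annotation: pd.DataFrame


def generate_bundle(config: SyntheticConfig | None = None,
                    enrichment_strength: float = 5.0,
                    network_p0: float = 0.02) -> SyntheticBundle:
    """Generate every pipeline input from one config (single entry point)."""
    config = config or SyntheticConfig()
    records = generate_inhibition_records(config)
    omics = generate_omics(config)
    params, truth = generate_dose_response(config, records, omics)
    network = generate_network(config, enrichment_strength, network_p0, truth)
    annotation = generate_kinase_annotation(config)
    return SyntheticBundle(config, records, omics, params, truth,
                           network, annotation)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["dose_grid"] = list(d["dose_grid"])
    d["potency_range"] = list(d["potency_range"])
    return d
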