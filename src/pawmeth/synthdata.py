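"""Synthetic inputs for every pipeline stage.

The study's raw material — HPLC-UV traces, per-field staining grades,
per-dog covariates, and EPIC-style beta/detection-p/bead-count tables — is
not publicly deposited, so this module generates statistically faithful
stand-ins. Defaults reproduce the published cohort structure: 10 control
vs 9 lymphoma dogs with group %5MeCyt means/SDs of 4.49/0.10 and 4.29/0.24,
H-score means/SDs of 227.5/15.9 and 208.7/14.1, a latent correlation of 0.5
between the two measurements, and an 8-sample (4+4) array experiment in
which roughly 34,574 of the human-designed probes hybridise in all canine
samples.

Every generator is a pure function of its spec plus a seed: identical
inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dm import m_to_beta

# Per-dog circulating lymphocyte counts (/uL) for the eight array-profiled
# dogs, as published in the cohort description table.
STAGE2_LYMPHOCYTES = {
    "lymphoma": {"L-01": 808, "L-03": 4580, "L-05": 1350, "L-08": 944},
    "control": {"C-04": 2208, "C-07": 1863, "C-08": 3212, "C-10": 2324},
}


def stage2_lymphocyte_counts() -> tuple[np.ndarray, np.ndarray]:
    """(lymphoma, control) lymphocyte-count vectors for the array cohort."""
    return (
        np.array(list(STAGE2_LYMPHOCYTES["lymphoma"].values()), dtype=float),
        np.array(list(STAGE2_LYMPHOCYTES["control"].values()), dtype=float),
    )


# ------------------------------------------------------------- chromatograms

@dataclass
class ChromSimSpec:
    """Gaussian-peaks-on-a-drifting-baseline model of an HPLC-UV trace.

    ``true_fraction`` is the molar fraction of methylated cytosine; the dC
    peak carries area (1 - f) * total_nmol and the 5MeCyt peak f * total_nmol
    under the identity calibration (1 area unit per nmol).
    """

    true_fraction: float = 0.0449
    total_nmol: float = 100.0
    peak_centers: tuple[float, float] = (6.0, 14.0)   # minutes: (dC, 5MeCyt)
    peak_sd: float = 0.25                              # minutes
    noise_sd: float = 0.0                              # detector units
    baseline_slope: float = 0.0                        # units / minute
    n_points: int = 4000
    t_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError("true_fraction must lie in [0, 1]")
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if self.peak_sd <= 0 or self.total_nmol <= 0:
            raise ValueError("peak_sd and total_nmol must be positive")
        c1, c2 = self.peak_centers
        if c1 == c2:
            raise ValueError("peak centers must be distinct")
        if abs(c2 - c1) < 4.0 * self.peak_sd:
            raise ValueError(
                "peaks overlap: center distance below 4 peak widths is rejected"
            )


def gen_chromatogram(spec: ChromSimSpec):
    """Simulate a two-peak trace; true peak areas go into the provenance."""
    from .hplc import Chromatogram

    rng = np.random.default_rng(spec.seed)
    c_dc, c_me = spec.peak_centers
    lo, hi = spec.t_range or (
        max(min(c_dc, c_me) - 8.0 * spec.peak_sd, 0.0),
        max(c_dc, c_me) + 8.0 * spec.peak_sd,
    )
    t = np.linspace(lo, hi, spec.n_points)
    area_dc = (1.0 - spec.true_fraction) * spec.total_nmol
    area_me = spec.true_fraction * spec.total_nmol
    norm = spec.peak_sd * np.sqrt(2.0 * np.pi)
    signal = spec.baseline_slope * t
    signal = signal + area_dc / norm * np.exp(-0.5 * ((t - c_dc) / spec.peak_sd) ** 2)
    signal = signal + area_me / norm * np.exp(-0.5 * ((t - c_me) / spec.peak_sd) ** 2)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=t.shape)
    meta = {
        "spec": asdict(spec),
        "true_area_dc": area_dc,
        "true_area_5me": area_me,
        "true_fraction": spec.true_fraction,
    }
    return Chromatogram(time=t, signal=signal, meta=meta)


def chromatogram_windows(spec: ChromSimSpec) -> dict[str, tuple[float, float]]:
    """Retention windows bracketing each generated peak at +-6 SD."""
    from .hplc import DC, ME

    c_dc, c_me = spec.peak_centers
    w = 6.0 * spec.peak_sd
    return {DC: (c_dc - w, c_dc + w), ME: (c_me - w, c_me + w)}


# --------------------------------------------------------------- ICC samples

def gen_icc_sample(
    n_fields: int,
    cells_per_field: int,
    grade_probs: Sequence[float],
    seed: int = 0,
    sample: str = "S1",
) -> pd.DataFrame:
    """Per-field multinomial draws of nucleus staining grades 0..3."""
    p = np.asarray(grade_probs, dtype=float)
    if p.shape != (4,):
        raise ValueError("grade_probs must have 4 entries")
    if np.any(p < 0):
        raise ValueError("grade probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("grade probabilities must sum to 1")
    if n_fields < 1 or cells_per_field < 1:
        raise ValueError("n_fields and cells_per_field must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(cells_per_field, p, size=n_fields)
    return pd.DataFrame(
        {
            "sample": sample,
            "field": np.arange(1, n_fields + 1),
            "grade0": counts[:, 0],
            "grade1": counts[:, 1],
            "grade2": counts[:, 2],
            "grade3": counts[:, 3],
        }
    )


# -------------------------------------------------------------------- cohort

@dataclass
class CohortSimSpec:
    """Two-group cohort with latently correlated (%5MeCyt, H-score) pairs.

    The pair is drawn per animal from a bivariate normal whose group means
    and SDs default to the published summary table and whose latent
    correlation defaults to the published Pearson r of 0.50. Ages are normal
    per group; lymphocyte counts log-normal (strictly positive,
    right-skewed), parameterised by natural-scale mean/SD.
    """

    n_control: int = 10
    n_case: int = 9
    hplc_mean_sd: dict = field(
        default_factory=lambda: {"control": (4.49, 0.10), "lymphoma": (4.29, 0.24)}
    )
    icc_mean_sd: dict = field(
        default_factory=lambda: {"control": (227.5, 15.9), "lymphoma": (208.7, 14.1)}
    )
    hplc_icc_corr: float = 0.50
    sex_probs: tuple[float, float] = (0.3, 0.7)  # (male, female)
    age_mean_sd: dict = field(
        default_factory=lambda: {"control": (7.7, 2.62), "lymphoma": (10.5, 3.04)}
    )
    lymphocyte_mean_sd: dict = field(
        default_factory=lambda: {"control": (2141.0, 660.0), "lymphoma": (4827.0, 8419.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("group sizes must be >= 2")
        if not -1.0 <= self.hplc_icc_corr <= 1.0:
            raise ValueError("latent correlation must lie in [-1, 1]")
        for d in (self.hplc_mean_sd, self.icc_mean_sd, self.lymphocyte_mean_sd):
            for _m, s in d.values():
                if s <= 0:
                    raise ValueError("SDs must be positive")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def gen_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """One cohort table: id, group, sex, age, age_bin, lymphocytes, %5me, H."""
    rng = np.random.default_rng(spec.seed)
    rho = spec.hplc_icc_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    rows = []
    for group, n, prefix in (
        ("control", spec.n_control, "C"),
        ("lymphoma", spec.n_case, "L"),
    ):
        mx, sx = spec.hplc_mean_sd[group]
        mh, sh = spec.icc_mean_sd[group]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        x = mx + sx * z[:, 0]
        h = mh + sh * z[:, 1]
        sex = rng.choice(["M", "F"], size=n, p=spec.sex_probs)
        ma, sa = spec.age_mean_sd[group]
        age = np.clip(rng.normal(ma, sa, size=n), 1.0, None)
        mu, sigma = _lognormal_params(*spec.lymphocyte_mean_sd[group])
        lymph = rng.lognormal(mu, sigma, size=n)
        for i in range(n):
            rows.append(
                {
                    "id": f"{prefix}-{i + 1:02d}",
                    "group": group,
                    "sex": sex[i],
                    "age": round(float(age[i]), 1),
                    "lymphocytes": round(float(lymph[i])),
                    "percent_5me": float(np.clip(x[i], 0.0, 100.0)),
                    "h_score": float(np.clip(h[i], 0.0, 300.0)),
                }
            )
    df = pd.DataFrame(rows)
    df["age_bin"] = np.where(df["age"] <= 10.0, "<=10", ">10")
    return df


def reference_cohort(seed: int = 0) -> pd.DataFrame:
    """A deterministic synthetic 19-dog cohort matching the published moments.

    The per-dog measurements of the study are not deposited, so this builds
    a synthetic stand-in whose group means and sample SDs equal the published
    summary values *exactly* (%5MeCyt: 4.49 +- 0.10 vs 4.29 +- 0.24; H-score:
    227.5 +- 15.9 vs 208.7 +- 14.1) and whose 19-dog Pearson correlation
    between %5MeCyt and H-score is exactly 0.50. Group-wise the construction
    standardises seeded normal draws to the target moments, then rotates the
    H-score component against an orthogonal residual so the pooled
    correlation hits the target.
    """
    spec = CohortSimSpec(seed=seed)
    rng = np.random.default_rng(seed)

    def standardized(n: int) -> np.ndarray:
        v = rng.normal(size=n)
        return (v - v.mean()) / v.std(ddof=1)

    def orthonormal_residual(x: np.ndarray) -> np.ndarray:
        e = rng.normal(size=x.size)
        e = e - e.mean()
        e = e - (e @ x) / (x @ x) * x
        return e / e.std(ddof=1)

    parts = {}
    for group, n in (("control", spec.n_control), ("lymphoma", spec.n_case)):
        mx, sx = spec.hplc_mean_sd[group]
        mh, sh = spec.icc_mean_sd[group]
        zx = standardized(n)
        ze = orthonormal_residual(zx)
        parts[group] = {"zx": zx, "ze": ze, "x": mx + sx * zx, "mh": mh, "sh": sh}

    x_all = np.concatenate([parts["control"]["x"], parts["lymphoma"]["x"]])

    def pooled_r(theta: float) -> float:
        hs = []
        for group in ("control", "lymphoma"):
            p = parts[group]
            zh = np.cos(theta) * p["zx"] + np.sin(theta) * p["ze"]
            hs.append(p["mh"] + p["sh"] * zh)
        h_all = np.concatenate(hs)
        return float(np.corrcoef(x_all, h_all)[0, 1])

    theta = brentq(lambda th: pooled_r(th) - spec.hplc_icc_corr, 0.0, np.pi)
    rows = []
    for group, prefix in (("control", "C"), ("lymphoma", "L")):
        p = parts[group]
        zh = np.cos(theta) * p["zx"] + np.sin(theta) * p["ze"]
        h = p["mh"] + p["sh"] * zh
        n = p["zx"].size
        sex = rng.choice(["M", "F"], size=n, p=spec.sex_probs)
        ma, sa = spec.age_mean_sd[group]
        age = np.clip(rng.normal(ma, sa, size=n), 1.0, None)
        mu, sigma = _lognormal_params(*spec.lymphocyte_mean_sd[group])
        lymph = rng.lognormal(mu, sigma, size=n)
        for i in range(n):
            rows.append(
                {
                    "id": f"{prefix}-{i + 1:02d}",
                    "group": group,
                    "sex": sex[i],
                    "age": round(float(age[i]), 1),
                    "lymphocytes": round(float(lymph[i])),
                    "percent_5me": float(p["x"][i]),
                    "h_score": float(h[i]),
                }
            )
    df = pd.DataFrame(rows)
    df["age_bin"] = np.where(df["age"] <= 10.0, "<=10", ">10")
    return df


# ------------------------------------------------------------ array experiment

@dataclass
class ArraySimSpec:
    """EPIC-style beta/detection-p/bead-count simulation with planted truth.

    A fraction ``frac_detectable`` of probes hybridise in every sample (the
    cross-species usable subset); the rest fail detection everywhere and
    their betas pile up near 0.3 as failed hybridisations do. Among
    detectable probes, ``frac_dm`` carry a planted group shift of
    ``effect_mean`` on the M scale, positive (hyper in the case group) with
    probability ``frac_hyper``. Baseline betas follow a three-mode mixture
    (unmethylated / hemimethylated / methylated); measurement noise is
    injected on the M scale where it is approximately homoscedastic.
    """

    n_probes: int = 10000
    n_per_group: int = 4
    frac_detectable: float = 0.35
    frac_dm: float = 0.0
    effect_mean: float = 2.0
    frac_hyper: float = 0.5
    beta_modes: tuple = ((2.0, 18.0), (20.0, 20.0), (18.0, 2.0))
    mode_weights: tuple[float, float, float] = (0.45, 0.10, 0.45)
    noise_sd_m: float = 0.4
    detection_fail_rate: float = 0.0
    low_bead_rate: float = 0.0
    n_genes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_detectable", "frac_dm", "frac_hyper",
                     "detection_fail_rate", "low_bead_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_mean < 0:
            raise ValueError("effect_mean must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.frac_dm > 0 and int(self.n_probes * self.frac_detectable * self.frac_dm) < 1:
            raise ValueError("frac_dm exceeds the detectable-probe budget: no probe to plant")


@dataclass
class TruthLabels:
    """Ground truth of a simulated array experiment."""

    detectable: np.ndarray   # bool per probe
    is_dm: np.ndarray        # bool per probe
    direction: np.ndarray    # +1 hyper / -1 hypo / 0 null, per probe


def gen_manifest(probe_ids: Sequence[str], n_genes: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic probe manifest: chromosome, CpG position, gene, region class."""
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "chromosome": rng.choice(chroms, size=n),
            "position": rng.integers(1, 3_000_000_00, size=n),
            "gene": rng.choice(genes, size=n),
            "region": rng.choice(["promoter", "body", "intergenic"], size=n, p=[0.3, 0.4, 0.3]),
        }
    )


def gen_array_experiment(spec: ArraySimSpec):
    """Simulate a :class:`~pawmeth.dm.BetaExperiment` plus its truth labels.

    Returns ``(exp, truth, manifest)``.
    """
    from .dm import BetaExperiment

    rng = np.random.default_rng(spec.seed)
    n, ns = spec.n_probes, 2 * spec.n_per_group
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")
    samples = pd.DataFrame(
        {
            "sample": [f"L-{i + 1:02d}" for i in range(spec.n_per_group)]
            + [f"C-{i + 1:02d}" for i in range(spec.n_per_group)],
            "group": ["lymphoma"] * spec.n_per_group + ["control"] * spec.n_per_group,
        }
    )
    case_mask = (samples["group"] == "lymphoma").to_numpy()

    detectable = np.zeros(n, dtype=bool)
    detectable[rng.permutation(n)[: int(round(n * spec.frac_detectable))]] = True

    # baseline betas: three-mode mixture for real probes
    comp = rng.choice(len(spec.beta_modes), size=n, p=spec.mode_weights)
    a = np.array([spec.beta_modes[c][0] for c in comp])
    b = np.array([spec.beta_modes[c][1] for c in comp])
    beta0 = rng.beta(a, b)
    m0 = np.log2(np.clip(beta0, 1e-6, 1 - 1e-6) / (1 - np.clip(beta0, 1e-6, 1 - 1e-6)))

    # planted effects among detectable probes
    is_dm = np.zeros(n, dtype=bool)
    direction = np.zeros(n, dtype=int)
    det_idx = np.flatnonzero(detectable)
    n_dm = int(round(det_idx.size * spec.frac_dm))
    if n_dm > 0:
        dm_idx = rng.choice(det_idx, size=n_dm, replace=False)
        is_dm[dm_idx] = True
        direction[dm_idx] = np.where(rng.random(n_dm) < spec.frac_hyper, 1, -1)

    M = m0[:, None] + spec.noise_sd_m * rng.normal(size=(n, ns))
    M[:, case_mask] += (spec.effect_mean * is_dm * direction)[:, None]
    beta = m_to_beta(M)
    # non-detectable probes: background signal piling up near beta ~ 0.3
    n_fail = int((~detectable).sum())
    beta[~detectable] = rng.beta(3.0, 7.0, size=(n_fail, ns))

    detp = np.empty((n, ns))
    detp[detectable] = rng.uniform(0.0, 0.01, size=(detectable.sum(), ns))
    detp[~detectable] = rng.uniform(0.06, 1.0, size=(n_fail, ns))
    beads = rng.poisson(14.0, size=(n, ns)) + 3

    # contamination among detectable probes
    if spec.detection_fail_rate > 0:
        hit = rng.random((n, ns)) < spec.detection_fail_rate
        hit[~detectable] = False
        detp[hit] = rng.uniform(0.06, 1.0, size=int(hit.sum()))
    if spec.low_bead_rate > 0:
        hit = rng.random((n, ns)) < spec.low_bead_rate
        hit[~detectable] = False
        beads[hit] = rng.integers(0, 3, size=int(hit.sum()))

    cols = samples["sample"].tolist()
    exp = BetaExperiment(
        beta=pd.DataFrame(beta, index=probe_ids, columns=cols),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=cols),
        bead_count=pd.DataFrame(beads, index=probe_ids, columns=cols),
        samples=samples,
    )
    truth = TruthLabels(detectable=detectable, is_dm=is_dm, direction=direction)
    n_genes = spec.n_genes or max(n // 10, 10)
    manifest = gen_manifest(probe_ids, n_genes=n_genes, seed=spec.seed + 1)
    return exp, truth, manifest


# ----------------------------------------------------------------- orthologs

def gen_ortholog_table(
    genes: Sequence[str],
    frac_homolog: float = 1.0,
    frac_ortholog: float = 525.0 / 748.0,
    seed: int = 0,
    assembly: str = "canFam3.1",
) -> pd.DataFrame:
    """Synthetic human-to-dog ortholog table.

    Each human gene independently receives a homolog flag with probability
    ``frac_homolog`` and an ortholog flag with probability ``frac_ortholog``;
    a dog symbol is assigned iff both flags are set. Default fractions give
    an expected 525 mapped genes out of 748 inputs, the published reduction.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols in input")
    for frac in (frac_homolog, frac_ortholog):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    homolog = rng.random(len(genes)) < frac_homolog
    ortholog = rng.random(len(genes)) < frac_ortholog
    both = homolog & ortholog
    return pd.DataFrame(
        {
            "human_gene": genes,
            "homolog": homolog,
            "ortholog": ortholog,
            "dog_gene": [f"cfa-{g}" if m else "" for g, m in zip(genes, both)],
            "assembly": assembly,
        }
    )


# ----------------------------------------------------------------- gene sets

def gen_gene_sets(
    genes: Sequence[str],
    n_terms: int = 50,
    size_range: tuple[int, int] = (10, 100),
    spike: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets over a universe, plus an optional spiked term.

    The spiked term contains exactly the designated foreground genes, giving
    a known best-ranking set for enrichment tests.
    """
    universe = list(genes)
    lo, hi = size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ValueError("size_range must fit inside the gene universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        sets[f"TERM{i:04d}"] = sorted(rng.choice(universe, size=size, replace=False))
    if spike is not None:
        term, members = spike
        stray = sorted(set(members) - set(universe))
        if stray:
            raise ValueError(f"spiked genes outside the universe: {stray[:10]}")
        sets[term] = sorted(set(members))
    return sets
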