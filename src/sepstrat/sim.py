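"""Synthetic early-sepsis cohort generator with planted ground truth.

Emulates the structure of a multi-site whole-blood RNA-seq sepsis study:
an ER discovery cohort, an independent ER validation cohort, an ICU cohort,
and healthy controls. Five latent endotypes each carry a block of uniquely
upregulated marker genes; severity (24h SOFA strata) and in-hospital
mortality carry their own planted gene programs. Counts follow a negative
binomial with per-gene baseline and dispersion and per-sample library-size
factors, the standard generative model for bulk RNA-seq.

Default clinical parameters follow the combined-cohort endotype ordering
reported for early sepsis: the neutrophilic-suppressive (NPS) and
inflammatory (INF) endotypes are the most severe (highest SOFA, mortality,
and blood-culture positivity), the innate-host-defence (IHD) endotype the
mildest of the common ones, and the adaptive (ADA) endotype the youngest
and least culture-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio

__all__ = ["SimConfig", "GroundTruth", "generate_cohort", "write_fixture", "read_fixture"]

ENDOTYPE_NAMES = ("NPS", "INF", "IHD", "IFN", "ADA")


@dataclass
class SimConfig:
    """Generative parameters for one synthetic study.

    Cohort sizes, endotype proportions, per-endotype SOFA models, mortality
    and blood-culture rates default to the combined discovery + validation
    clinical table of the emulated study design.
    """

    n_er_discovery: int = 182
    n_er_validation: int = 84
    n_icu: int = 82
    n_healthy: int = 39
    n_genes: int = 8000
    k_endotypes: int = 5
    markers_per_endotype: int = 220
    marker_log2fc_range: tuple[float, float] = (1.0, 2.5)
    n_severity_genes: int = 150
    severity_log2fc: float = 1.0
    n_mortality_genes: int = 100
    mortality_log2fc: float = 1.0
    baseline_mean_logmu: tuple[float, float] = (3.0, 1.5)
    dispersion_range: tuple[float, float] = (0.05, 0.5)
    libsize_sd: float = 0.2
    # combined-cohort endotype sizes 83/45/55/58/25 of 266
    endotype_proportions: tuple[float, ...] = (
        83 / 266,
        45 / 266,
        55 / 266,
        58 / 266,
        25 / 266,
    )
    # per-endotype mean/sd of 24h SOFA in ER cohorts (severity ranking
    # NPS > INF > IFN ~ ADA > IHD) and the scaled-up ICU analogue
    sofa_mean: tuple[float, ...] = (2.5, 2.2, 1.4, 1.8, 1.7)
    sofa_sd: tuple[float, ...] = (2.2, 2.1, 1.6, 1.8, 1.7)
    icu_sofa_mean: tuple[float, ...] = (7.6, 8.2, 3.5, 3.7, 3.5)
    icu_sofa_sd: tuple[float, ...] = (5.2, 4.4, 3.3, 3.9, 3.5)
    mortality_rates: tuple[float, ...] = (0.20, 0.16, 0.06, 0.08, 0.03)
    icu_mortality_rates: tuple[float, ...] = (0.45, 0.26, 0.05, 0.05, 0.05)
    blood_culture_rates: tuple[float, ...] = (0.284, 0.289, 0.148, 0.089, 0.042)
    hospital_stay_mean: tuple[float, ...] = (9.6, 7.8, 4.9, 7.6, 5.3)
    age_mean: tuple[float, ...] = (59.4, 58.3, 62.7, 51.2, 37.2)
    seed: int = 0

    def validate(self) -> None:
        k = self.k_endotypes
        if abs(sum(self.endotype_proportions) - 1.0) > 1e-9:
            raise ValueError("endotype_proportions must sum to 1")
        if self.markers_per_endotype * k > self.n_genes:
            raise ValueError("markers_per_endotype * k_endotypes exceeds n_genes")
        per_endotype = {
            "endotype_proportions": self.endotype_proportions,
            "sofa_mean": self.sofa_mean,
            "sofa_sd": self.sofa_sd,
            "icu_sofa_mean": self.icu_sofa_mean,
            "icu_sofa_sd": self.icu_sofa_sd,
            "mortality_rates": self.mortality_rates,
            "icu_mortality_rates": self.icu_mortality_rates,
            "blood_culture_rates": self.blood_culture_rates,
            "hospital_stay_mean": self.hospital_stay_mean,
            "age_mean": self.age_mean,
        }
        for name, vec in per_endotype.items():
            if len(vec) != k:
                raise ValueError(f"{name} must have length k_endotypes={k}")
        for name in ("mortality_rates", "icu_mortality_rates", "blood_culture_rates"):
            if any(not 0 <= r <= 1 for r in getattr(self, name)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if (self.markers_per_endotype * k + self.n_severity_genes + self.n_mortality_genes) > self.n_genes:
            raise ValueError("planted gene programs exceed n_genes; allocation would overlap")

    @property
    def endotype_names(self) -> tuple[str, ...]:
        if self.k_endotypes == len(ENDOTYPE_NAMES):
            return ENDOTYPE_NAMES
        return tuple(f"E{i + 1}" for i in range(self.k_endotypes))


@dataclass
class GroundTruth:
    endotype_label: pd.Series  # per septic sample, endotype name
    marker_genes: dict[str, list[str]]  # per endotype, pairwise disjoint
    severity_genes: list[str]
    mortality_genes: list[str]
    true_log2fc: dict[str, float]  # planted per-gene effect size
    config: SimConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.marker_genes.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"marker sets are not disjoint ({name}: {sorted(overlap)[:3]}...)")
            seen |= set(genes)


def _sample_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = config.endotype_names
    rows = []
    counters = {"ERD": 0, "ERV": 0, "ICU": 0, "HC": 0}

    def new_id(prefix: str) -> str:
        counters[prefix] += 1
        return f"{prefix}{counters[prefix]:04d}"

    cohort_plan = [
        ("ER_discovery", "ERD", config.n_er_discovery, False),
        ("ER_validation", "ERV", config.n_er_validation, False),
        ("ICU", "ICU", config.n_icu, True),
        ("healthy", "HC", config.n_healthy, None),
    ]
    props = np.asarray(config.endotype_proportions)
    for cohort, prefix, n, is_icu in cohort_plan:
        if is_icu is None:  # healthy controls: no endotype, no planted effects
            for _ in range(n):
                rows.append(
                    {
                        "sample_id": new_id(prefix),
                        "cohort": cohort,
                        "endotype": "",
                        "sofa24": np.nan,
                        "sofa72": np.nan,
                        "qsofa": 0,
                        "died_in_hospital": False,
                        "survival_time_days": 28.0,
                        "event": False,
                        "blood_culture_positive": False,
                        "age": float(np.clip(rng.normal(50, 15), 19, 96)),
                        "sex": "F" if rng.random() < 0.5 else "M",
                    }
                )
            continue
        e_idx = rng.choice(config.k_endotypes, size=n, p=props)
        sofa_mu = config.icu_sofa_mean if is_icu else config.sofa_mean
        sofa_sd = config.icu_sofa_sd if is_icu else config.sofa_sd
        mort = config.icu_mortality_rates if is_icu else config.mortality_rates
        for e in e_idx:
            sofa24 = int(np.clip(round(rng.normal(sofa_mu[e], sofa_sd[e])), 0, 24))
            sofa72 = int(np.clip(round(sofa24 + rng.normal(-0.5, 1.5)), 0, 24))
            died = bool(rng.random() < mort[e])
            stay = float(max(1.0, rng.lognormal(np.log(config.hospital_stay_mean[e]), 0.6)))
            if died:
                time, event = float(rng.uniform(1.0, 28.0)), True
            else:
                time, event = min(stay, 28.0), False
            rows.append(
                {
                    "sample_id": new_id(prefix),
                    "cohort": cohort,
                    "endotype": names[e],
                    "sofa24": sofa24,
                    "sofa72": sofa72,
                    "qsofa": int(np.clip(round(sofa24 / 4 + rng.normal(0, 0.5)), 0, 3)),
                    "died_in_hospital": died,
                    "survival_time_days": round(time, 2),
                    "event": event,
                    "blood_culture_positive": bool(rng.random() < config.blood_culture_rates[e]),
                    "age": float(np.clip(rng.normal(config.age_mean[e], 15), 19, 96)),
                    "sex": "F" if rng.random() < 0.45 else "M",
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return meta


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (counts genes x samples, sample metadata, ground truth).

    Counts: K_ij ~ NB(mean = s_j * mu_i * 2^beta_ij, var = m + phi_i m^2)
    where beta_ij is the planted log2 effect when gene i belongs to sample
    j's endotype marker set, or to the severity program (full effect for
    High-severity samples, half for Intermediate) or mortality program
    (deceased samples). Healthy controls carry no planted effects.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_clinical, rng_counts = (np.random.default_rng(c) for c in ss.spawn(3))

    g = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    mu = rng_genes.lognormal(*config.baseline_mean_logmu, size=g)
    phi = rng_genes.uniform(*config.dispersion_range, size=g)

    # disjoint allocation of planted gene programs
    perm = rng_genes.permutation(g)
    pos = 0
    names = config.endotype_names
    marker_genes: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for name in names:
        idx = perm[pos : pos + config.markers_per_endotype]
        marker_idx[name] = idx
        marker_genes[name] = [gene_ids[i] for i in idx]
        pos += config.markers_per_endotype
    sev_idx = perm[pos : pos + config.n_severity_genes]
    pos += config.n_severity_genes
    mort_idx = perm[pos : pos + config.n_mortality_genes]

    lo, hi = config.marker_log2fc_range
    true_log2fc: dict[str, float] = {}
    marker_fc: dict[str, np.ndarray] = {}
    for name in names:
        fc = rng_genes.uniform(lo, hi, size=len(marker_idx[name]))
        marker_fc[name] = fc
        for i, v in zip(marker_idx[name], fc):
            true_log2fc[gene_ids[i]] = float(v)
    for i in sev_idx:
        true_log2fc[gene_ids[i]] = float(config.severity_log2fc)
    for i in mort_idx:
        true_log2fc[gene_ids[i]] = float(config.mortality_log2fc)

    meta = _sample_frame(config, rng_clinical)
    n = len(meta)
    s = rng_clinical.lognormal(0.0, config.libsize_sd, size=n)
    s = s / np.exp(np.mean(np.log(s)))

    beta = np.zeros((g, n))
    septic = meta["cohort"] != "healthy"
    for name in names:
        cols = np.flatnonzero((meta["endotype"] == name).to_numpy())
        if cols.size:
            beta[np.ix_(marker_idx[name], cols)] = marker_fc[name][:, None]
    sofa = meta["sofa24"].to_numpy()
    high = np.flatnonzero(septic.to_numpy() & (sofa >= 5))
    inter = np.flatnonzero(septic.to_numpy() & (sofa >= 2) & (sofa < 5))
    if config.n_severity_genes:
        beta[np.ix_(sev_idx, high)] = config.severity_log2fc
        beta[np.ix_(sev_idx, inter)] = config.severity_log2fc / 2.0
    died = np.flatnonzero(septic.to_numpy() & meta["died_in_hospital"].to_numpy())
    if config.n_mortality_genes:
        beta[np.ix_(mort_idx, died)] = config.mortality_log2fc

    mean = s[None, :] * mu[:, None] * np.power(2.0, beta)
    r = 1.0 / phi[:, None]
    p = r / (r + mean)
    counts = rng_counts.negative_binomial(r, p).astype(int)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=meta.index)

    truth = GroundTruth(
        endotype_label=meta.loc[septic, "endotype"].copy(),
        marker_genes=marker_genes,
        severity_genes=[gene_ids[i] for i in sev_idx],
        mortality_genes=[gene_ids[i] for i in mort_idx],
        true_log2fc=true_log2fc,
        config=config,
    )
    return counts_df, meta, truth


def write_fixture(
    counts: pd.DataFrame, meta: pd.DataFrame, truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """Write counts TSV, metadata TSV, marker GMT and ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": sio.write_counts(counts, directory / "counts.tsv"),
        "metadata": sio.write_metadata(meta, directory / "metadata.tsv"),
        "markers_gmt": sio.write_gmt(
            truth.marker_genes, directory / "markers.gmt", description="planted endotype markers"
        ),
        "truth_json": sio.write_json(
            {
                "endotype_label": truth.endotype_label.to_dict(),
                "severity_genes": truth.severity_genes,
                "mortality_genes": truth.mortality_genes,
                "true_log2fc": truth.true_log2fc,
                "config": asdict(truth.config) if truth.config else None,
            },
            directory / "ground_truth.json",
        ),
    }
    return paths


def read_fixture(directory: str | Path):
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    counts = sio.read_counts(directory / "counts.tsv")
    meta = sio.read_metadata(directory / "metadata.tsv")
    markers = sio.read_gmt(directory / "markers.gmt")
    truth_raw = sio.read_json(directory / "ground_truth.json")
    cfg = SimConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in truth_raw["config"].items()}) if truth_raw.get("config") else None
    truth = GroundTruth(
        endotype_label=pd.Series(truth_raw["endotype_label"]),
        marker_genes=markers,
        severity_genes=truth_raw["severity_genes"],
        mortality_genes=truth_raw["mortality_genes"],
        true_log2fc=truth_raw["true_log2fc"],
        config=cfg,
    )
    return counts, meta, truth
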