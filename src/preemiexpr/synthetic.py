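"""Synthetic preterm-cohort generator.

Emulates the statistical structure the analysis pipeline assumes: a
negative-binomial gene x subject count matrix with subject-specific
sequencing depth, gestational ages spanning 23-41 weeks with an extremely
preterm (<29 wk) subgroup, BPD assigned within that subgroup and PRD across
the cohort (both via logistic links in gestational age calibrated to the
configured marginal prevalences), daily oxygen traces whose severity rises
with prematurity and BPD, correlated within-pathway gene blocks driven by
latent factors, and planted outcome-associated genes with modest fold
changes.  The ground truth of every planted effect is serialized alongside
the data so recovery tests are self-contained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .oxygen import OxygenTrace, label_bpd_rac, qualifying_oxygen_days
from .pathways import GeneSetCollection, write_gmt

TRUTH_SCHEMA_VERSION = 1


@dataclass
class SimulationConfig:
    """Study-condition defaults mirror the profiled cohort: 145 subjects
    (72 extremely preterm), ~13.5k expressed genes, depth CV ~0.37,
    BPD prevalence 34/72 among <29 wk, PRD prevalence 70/116 with ~11%
    missing, planted fold changes below 2."""

    n_subjects: int = 145
    n_genes: int = 13455
    n_pathways: int = 1330
    genes_per_pathway: tuple[int, int] = (5, 30)
    depth_lognormal_params: tuple[float, float] = (0.0, 0.36)
    nb_dispersion: float = 0.08
    frac_signal_genes: float = 501 / 13455
    signal_log2fc: float = 0.8
    within_pathway_correlation: float = 0.3
    gab_range_weeks: tuple[float, float] = (23.0, 41.0)
    bpd_prevalence_lt29: float = 34 / 72
    prd_prevalence: float = 70 / 116
    prd_missing_rate: float = 14 / 130
    frac_lt29: float = 72 / 145
    biological_log_sd: float = 0.5
    baseline_log_mean: float = 5.0    # natural-log scale, median ~150 counts
    baseline_log_sd: float = 1.3
    pathway_overlap_prob: float = 0.05
    signal_outcome: str = "bpd_shennan"   # or "prd"
    signal_in_pathways: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_signal_genes", "within_pathway_correlation",
                     "bpd_prevalence_lt29", "prd_prevalence",
                     "prd_missing_rate", "frac_lt29", "pathway_overlap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.within_pathway_correlation >= 1.0:
            raise ValueError("within_pathway_correlation must be < 1")
        for name in ("n_subjects", "n_genes", "n_pathways"):
            if getattr(self, name) < 0 or (name != "n_pathways" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        lo, hi = self.gab_range_weeks
        if not (22.0 <= lo < hi <= 42.0):
            raise ValueError("gab range must lie within [22, 42] weeks")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if round(self.frac_signal_genes * self.n_genes) > self.n_genes:
            raise ValueError("signal genes exceed total genes")
        if self.signal_outcome not in ("bpd_shennan", "prd"):
            raise ValueError("signal_outcome must be 'bpd_shennan' or 'prd'")


@dataclass
class SubjectRecord:
    subject_id: str
    gab_weeks: float
    sex: str
    race: str
    birth_weight_g: float
    bpd_shennan: str
    bpd_rac: str
    prd: str
    prd_missing: bool
    oxygen: OxygenTrace = field(repr=False)


@dataclass
class SyntheticCohort:
    counts: CountMatrix
    subjects: list[SubjectRecord]
    gene_sets: GeneSetCollection
    truth: dict

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "subject_id": s.subject_id,
                "gab_weeks": round(s.gab_weeks, 3),
                "sex": s.sex,
                "race": s.race,
                "birth_weight_g": round(s.birth_weight_g, 1),
                "bpd_shennan": s.bpd_shennan,
                "bpd_rac": s.bpd_rac,
                "prd": s.prd,
                "prd_missing": s.prd_missing,
            }
            for s in self.subjects
        ]).set_index("subject_id")

    def flowsheet_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:
            df = s.oxygen.daily.copy()
            df.insert(0, "subject_id", s.subject_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _solve_logistic_intercept(gab: np.ndarray, slope: float, target: float) -> float:
    """Intercept a such that mean sigmoid(a - slope * gab_centered) = target."""
    centered = gab - gab.mean()
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        mean_p = float(np.mean(1.0 / (1.0 + np.exp(-(mid - slope * centered)))))
        if mean_p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _outcome_probs(gab: np.ndarray, slope: float, target: float) -> np.ndarray:
    a = _solve_logistic_intercept(gab, slope, target)
    return 1.0 / (1.0 + np.exp(-(a - slope * (gab - gab.mean()))))


def simulate_oxygen_trace(gab_weeks: float, bpd_label: bool, seed: int,
                          birth_weight_g: float = 1000.0,
                          n_days: int = 28) -> OxygenTrace:
    """Daily noon FiO2/support records for one subject.

    Severity follows a declining-exponential FiO2 trajectory whose amplitude
    grows with prematurity and with a BPD label, floored at room air; term
    subjects without BPD stay on room air throughout.  No clinical claim is
    intended beyond monotonicity in severity.
    """
    if not 22.0 <= gab_weeks <= 42.0:
        raise ValueError("gestational age out of range")
    rng = np.random.default_rng(seed)
    amplitude = max(0.0, 0.035 * (31.0 - gab_weeks)) * (1.5 if bpd_label else 1.0)
    days = np.arange(1, n_days + 1)
    if amplitude > 0:
        fio2 = 0.21 + amplitude * np.exp(-(days - 1) / 12.0) \
            + rng.normal(0.0, 0.02, n_days)
        fio2 = np.clip(fio2, 0.21, 1.0)
    else:
        fio2 = np.full(n_days, 0.21)
    mode = np.where(fio2 > 0.45, "vent",
                    np.where(fio2 > 0.30, "cpap",
                             np.where(fio2 > 0.22, "low_flow_cannula", "room_air")))
    flow = np.where(mode == "low_flow_cannula",
                    np.round(rng.uniform(0.5, 2.0, n_days), 2), 0.0)
    pressure = np.where(mode == "vent", 18.0, np.where(mode == "cpap", 6.0, 0.0))
    daily = pd.DataFrame({
        "day": days,
        "fio2": np.round(fio2, 4),
        "support_mode": mode,
        "flow_lpm": flow.astype(float),
        "pressure_cmH2O": pressure,
    })
    return OxygenTrace("synthetic", daily, birth_weight_g)


def _make_gene_sets(rng: np.random.Generator, config: SimulationConfig,
                    gene_ids: np.ndarray) -> tuple[GeneSetCollection, np.ndarray]:
    """Mostly-disjoint pathway blocks with occasional shared members.

    Returns the collection plus each gene's latent-factor id (-1 = none):
    the factor of the first pathway the gene was assigned to.
    """
    lo, hi = config.genes_per_pathway
    factor_of_gene = np.full(config.n_genes, -1, dtype=int)
    sets: dict[str, list[str]] = {}
    cursor = 0
    for p in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        for _ in range(size):
            if cursor > 0 and rng.random() < config.pathway_overlap_prob:
                members.append(gene_ids[int(rng.integers(0, cursor))])
            elif cursor < config.n_genes:
                members.append(gene_ids[cursor])
                factor_of_gene[cursor] = p
                cursor += 1
        members = list(dict.fromkeys(members))
        if members:
            sets[f"PW{p + 1:04d}"] = members
    return GeneSetCollection(sets, source="synthetic"), factor_of_gene


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort under the configured study conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, G = config.n_subjects, config.n_genes
    subject_ids = np.array([f"S{i + 1:04d}" for i in range(n)])
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(G)])

    # --- demographics ------------------------------------------------------
    lo, hi = config.gab_range_weeks
    if hi <= 29.0 or lo >= 29.0:
        gab = rng.uniform(lo, hi, n)
    else:
        n_lt = int(round(config.frac_lt29 * n))
        gab = np.concatenate([rng.uniform(lo, 29.0, n_lt),
                              rng.uniform(29.0, hi, n - n_lt)])
        rng.shuffle(gab)
    sex = rng.choice(["male", "female"], n)
    race = rng.choice(["white", "black", "other"], n, p=[0.6, 0.25, 0.15])
    bw = 650.0 * np.exp(0.105 * (gab - 24.0)) * rng.lognormal(0.0, 0.12, n)

    # --- outcomes ----------------------------------------------------------
    # slopes calibrated so the simulated GAB gap between outcome groups
    # matches the profiled cohort (~0.8 wk for BPD among <29 wk, ~2.6 wk for PRD)
    lt29 = gab < 29.0
    bpd = np.zeros(n, dtype=bool)
    if lt29.any():
        p_bpd = _outcome_probs(gab[lt29], slope=0.3, target=config.bpd_prevalence_lt29)
        bpd[lt29] = rng.random(lt29.sum()) < p_bpd
    prd_missing = rng.random(n) < config.prd_missing_rate
    p_prd = _outcome_probs(gab, slope=0.10, target=config.prd_prevalence)
    prd = rng.random(n) < p_prd

    # --- oxygen traces and the RAC label ----------------------------------
    trace_seeds = rng.integers(0, 2 ** 31 - 1, n)
    traces, bpd_rac = [], []
    for i in range(n):
        trace = simulate_oxygen_trace(gab[i], bool(bpd[i]), int(trace_seeds[i]),
                                      birth_weight_g=float(bw[i]))
        trace.subject_id = subject_ids[i]
        traces.append(trace)
        if qualifying_oxygen_days(trace) >= 28:
            fail_p = 0.7 if bpd[i] else 0.1
            rac_result = "fail" if rng.random() < fail_p else "pass"
        else:
            rac_result = "not_done"
        bpd_rac.append(label_bpd_rac(trace, rac_result))

    # --- gene sets and latent factors --------------------------------------
    gene_sets, factor_of_gene = _make_gene_sets(rng, config, gene_ids)

    # --- planted signal -----------------------------------------------------
    n_signal = int(round(config.frac_signal_genes * G))
    base_log_mean = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)
    signal_pathways: list[str] = []
    if n_signal == 0:
        signal_idx = np.array([], dtype=int)
    elif config.signal_in_pathways:
        chosen: list[int] = []
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for name in gene_sets.sets:
            if len(chosen) >= n_signal:
                break
            signal_pathways.append(name)
            chosen.extend(gene_pos[g] for g in gene_sets.sets[name])
        signal_idx = np.array(chosen[:n_signal] if len(chosen) > n_signal else chosen,
                              dtype=int)
    else:
        expressed = np.where(base_log_mean > np.log(20.0))[0]
        pool = expressed if expressed.size >= n_signal else np.arange(G)
        signal_idx = rng.choice(pool, size=n_signal, replace=False)

    outcome_pos = bpd if config.signal_outcome == "bpd_shennan" else prd
    delta = np.zeros(G)
    delta[signal_idx] = config.signal_log2fc

    # --- counts -------------------------------------------------------------
    mu_d, sd_d = config.depth_lognormal_params
    depth = rng.lognormal(mu_d, sd_d, n)
    depth = depth / depth.mean()
    rho = config.within_pathway_correlation
    sigma_b = config.biological_log_sd
    z = rng.standard_normal((config.n_pathways, n)) if config.n_pathways else np.zeros((1, n))
    eps = rng.standard_normal((G, n))
    shared = np.where(factor_of_gene[:, None] >= 0,
                      z[np.maximum(factor_of_gene, 0), :], 0.0)
    has_factor = factor_of_gene >= 0
    bio = sigma_b * np.where(has_factor[:, None],
                             np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps,
                             eps)
    log_mean = (base_log_mean[:, None] - 0.5 * sigma_b ** 2 + bio
                + np.log(depth)[None, :]
                + np.log(2.0) * delta[:, None] * outcome_pos[None, :].astype(float))
    mean = np.exp(np.clip(log_mean, None, 13.0))  # cap ~4.4e5 counts
    phi = config.nb_dispersion
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)
    count_matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=subject_ids))

    subjects = [
        SubjectRecord(
            subject_id=subject_ids[i],
            gab_weeks=float(gab[i]),
            sex=str(sex[i]),
            race=str(race[i]),
            birth_weight_g=float(bw[i]),
            bpd_shennan=("yes" if bpd[i] else "no") if lt29[i] else (
                "no" if bw[i] < 1500 else "not_applicable"),
            bpd_rac=bpd_rac[i],
            prd="missing" if prd_missing[i] else ("yes" if prd[i] else "no"),
            prd_missing=bool(prd_missing[i]),
            oxygen=traces[i],
        )
        for i in range(n)
    ]
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "seed": config.seed,
        "signal_genes": {gene_ids[i]: float(config.signal_log2fc) for i in sorted(signal_idx)},
        "signal_pathways": signal_pathways,
        "signal_outcome": config.signal_outcome,
        # JSON-canonical form (tuples become lists) so the serialized truth
        # round-trips exactly
        "config": json.loads(json.dumps(asdict(config))),
    }
    return SyntheticCohort(count_matrix, subjects, gene_sets, truth)


# ------------------------------------------------------------------ fixtures

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as plain-text interchange files plus a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.counts.to_tsv(directory / "counts.tsv")
    cohort.counts.to_mtx(directory / "counts")
    cohort.metadata_frame().to_csv(directory / "metadata.tsv", sep="\t")
    cohort.flowsheet_frame().to_csv(directory / "flowsheet.tsv", sep="\t", index=False)
    write_gmt(cohort.gene_sets, directory / "gene_sets.gmt")
    (directory / "truth.json").write_text(
        json.dumps(cohort.truth, indent=2, sort_keys=True) + "\n")
    files = sorted(p.name for p in directory.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {"files": {name: _sha256(directory / name) for name in files}}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_fixture_set(directory: str | Path) -> SyntheticCohort:
    """Round-trip reader for :func:`write_fixture_set` outputs."""
    from .pathways import read_gmt

    directory = Path(directory)
    counts = CountMatrix.from_tsv(directory / "counts.tsv")
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col="subject_id")
    flow = pd.read_csv(directory / "flowsheet.tsv", sep="\t")
    gene_sets = read_gmt(directory / "gene_sets.gmt")
    truth = json.loads((directory / "truth.json").read_text())
    subjects = []
    for sid, row in meta.iterrows():
        daily = flow.loc[flow["subject_id"] == sid].drop(columns="subject_id")
        daily = daily.reset_index(drop=True)
        trace = OxygenTrace(sid, daily, float(row["birth_weight_g"]))
        subjects.append(SubjectRecord(
            subject_id=sid, gab_weeks=float(row["gab_weeks"]), sex=row["sex"],
            race=row["race"], birth_weight_g=float(row["birth_weight_g"]),
            bpd_shennan=row["bpd_shennan"], bpd_rac=row["bpd_rac"],
            prd=row["prd"], prd_missing=bool(row["prd_missing"]), oxygen=trace))
    return SyntheticCohort(counts, subjects, gene_sets, truth)
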