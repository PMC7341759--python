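"""Synthetic paired tumor/non-tumor cohort generator with planted structure.

The generator emulates a log2-intensity microarray cohort: each patient
contributes one tumor (T) and one non-tumor (NT) sample.  Co-expression
modules are planted through a shared latent factor per sample,

    x_fs = mu_f + b * z_s + delta_tumor * 1[tumor]
           + phenotype_effect * 1[tumor, poor patient] + eps_fs,

with z standardized to zero mean within each tissue compartment and unit
variance overall, so the planted tumor shift is the only systematic
T-vs-NT difference and the within-module correlation has closed form
r = b^2 / (b^2 + sigma^2).  Non-module features carry an independent
per-patient biological effect (shared by a patient's T and NT sample, so
it cancels from the paired test); this is what keeps unrelated
differentially expressed features from correlating strongly merely by
sharing the tumor/non-tumor contrast.  Clinical phenotype labels for a linked group
are thresholded on the patient's tumor-sample latent factor (high factor
means poor when the phenotype effect is non-negative, low factor means
poor otherwise), guaranteeing a real expression-phenotype link for
recovery tests.  Survival times are exponential with hazard
lambda0 * exp(hazard_beta * z_tumor); censoring is independent uniform
administrative censoring C ~ U(0, c_max), with c_max chosen so that the
expected censored fraction at the baseline hazard equals the configured
rate.

Everything drawn from a single seeded generator in fixed order, so the
same configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    ExpressionMatrix,
    write_bed,
    write_clinical,
    write_design,
    write_expression,
    write_gmt,
    write_json,
    read_json,
)

LINKABLE_GROUPS = ("tumor_properties", "grade", "capsule", "invasion", "survival", "none")
N_DECOY_SETS = 10
DECOY_SET_SIZE = 20


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    n_lnc_members: int
    n_mrna_members: int
    target_r: float = 0.9
    tumor_shift: float = 0.0
    linked_group: str = "none"
    phenotype_effect: float = 0.0
    hazard_beta: float = 0.0

    def validate(self, i: int) -> None:
        if self.n_lnc_members < 1 or self.n_mrna_members < 1:
            raise ConfigError(f"modules[{i}]: member counts must be positive")
        if not 0.0 < self.target_r < 1.0:
            raise ConfigError(f"modules[{i}].target_r must be in (0, 1)")
        if abs(self.tumor_shift) >= 6:
            raise ConfigError(f"modules[{i}].tumor_shift must satisfy |shift| < 6")
        if self.linked_group not in LINKABLE_GROUPS:
            raise ConfigError(
                f"modules[{i}].linked_group must be one of {LINKABLE_GROUPS}"
            )


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror a 49-patient paired microarray cohort: baseline
    intensities uniform on 6..14 log2 units, residual noise 0.3 log2
    units, 5% of non-module features carrying a background tumor shift of
    1.5 log2 units, and 30% uniform censoring of survival.
    """

    n_patients: int = 49
    n_lnc: int = 2000
    n_mrna: int = 2000
    modules: list[ModuleSpec] = field(default_factory=list)
    baseline_mean_range: tuple[float, float] = (6.0, 14.0)
    feature_noise_sd: float = 0.3
    biological_sd: float = 0.5
    de_background_fraction: float = 0.05
    de_background_shift: float = 1.5
    censoring_rate: float = 0.3
    baseline_hazard: float = math.log(2) / 730.0  # per day; 2-year median at z = 0
    poor_quantile: float = 0.5
    flag_absent_quantile: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 3:
            raise ConfigError("n_patients must be >= 3")
        if self.n_lnc < 1 or self.n_mrna < 1:
            raise ConfigError("n_lnc and n_mrna must be positive")
        for frac_name in ("de_background_fraction", "censoring_rate",
                          "poor_quantile", "flag_absent_quantile"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac_name} must be in [0, 1]")
        if self.censoring_rate >= 1.0:
            raise ConfigError("censoring_rate must be < 1")
        if self.feature_noise_sd < 0:
            raise ConfigError("feature_noise_sd must be >= 0")
        if self.biological_sd < 0:
            raise ConfigError("biological_sd must be >= 0")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ConfigError("baseline_mean_range must be an increasing interval")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        for i, mod in enumerate(self.modules):
            mod.validate(i)
        if sum(m.n_lnc_members for m in self.modules) > self.n_lnc:
            raise ConfigError("modules: lncRNA member counts exceed n_lnc")
        if sum(m.n_mrna_members for m in self.modules) > self.n_mrna:
            raise ConfigError("modules: mRNA member counts exceed n_mrna")


def expected_module_r(loading: float, noise_sd: float) -> float:
    """Closed-form within-module correlation b^2 / (b^2 + sigma^2)."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if loading == 0 and noise_sd == 0:
        raise ConfigError("expected_module_r undefined for loading = noise_sd = 0")
    b2 = float(loading) ** 2
    return b2 / (b2 + float(noise_sd) ** 2)


def module_loading(target_r: float, noise_sd: float) -> float:
    """Loading b that realizes ``target_r`` at the given noise level."""
    if noise_sd == 0.0:
        return 1.0  # any non-zero loading gives r = 1 without noise
    return noise_sd * math.sqrt(target_r / (1.0 - target_r))


@dataclass
class TruthRecord:
    """Machine-readable record of everything the generator planted."""

    modules: list[dict]
    de_direction: dict  # feature_id -> up/down, planted features only
    clinical_links: dict  # group -> {module, direction}
    latent: dict  # module index (str) -> {patient_id: tumor-sample z}
    phenotype_labels: dict  # group -> {patient_id: good/poor}
    censored: dict  # patient_id -> bool

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**{k: d[k] for k in (
            "modules", "de_direction", "clinical_links", "latent",
            "phenotype_labels", "censored",
        )})

    def to_json(self, path) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        return cls.from_dict(read_json(path))

    def module_members(self, index: int) -> tuple[list[str], list[str]]:
        mod = self.modules[index]
        return list(mod["lnc_members"]), list(mod["mrna_members"])


@dataclass
class SimCohort:
    expression: ExpressionMatrix
    design: pd.DataFrame
    clinical: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: dict
    truth: TruthRecord


def _standardized_latent(rng, is_tumor: np.ndarray) -> np.ndarray:
    """Latent factor per sample: zero mean within each tissue, unit variance."""
    z = rng.normal(size=is_tumor.size)
    z = z.copy()
    z[is_tumor] -= z[is_tumor].mean()
    z[~is_tumor] -= z[~is_tumor].mean()
    sd = z.std()
    if sd == 0.0:
        return z
    return z / sd


def generate_cohort(config: SimConfig) -> SimCohort:
    """Generate a paired cohort with planted modules and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    sample_ids, patient_col, tissue_col = [], [], []
    for p in patients:
        for tissue in ("T", "NT"):
            sample_ids.append(f"{p}_{tissue}")
            patient_col.append(p)
            tissue_col.append(tissue)
    design = pd.DataFrame(
        {"sample_id": sample_ids, "patient_id": patient_col, "tissue": tissue_col}
    )
    is_tumor = np.asarray([t == "T" for t in tissue_col])
    tumor_cols = np.where(is_tumor)[0]

    lnc_ids = [f"LNC{i + 1:05d}" for i in range(config.n_lnc)]
    mrna_ids = [f"MRNA{i + 1:05d}" for i in range(config.n_mrna)]
    feature_ids = lnc_ids + mrna_ids
    n_feat, n_samp = len(feature_ids), len(sample_ids)

    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, size=n_feat)
    X = mu[:, None] + rng.normal(0.0, config.feature_noise_sd, size=(n_feat, n_samp))

    # module member indices come from the front of each id pool
    module_rows: list[np.ndarray] = []
    lnc_cursor = 0
    mrna_cursor = len(lnc_ids)
    module_meta = []
    for k, mod in enumerate(config.modules):
        lrows = np.arange(lnc_cursor, lnc_cursor + mod.n_lnc_members)
        mrows = np.arange(mrna_cursor, mrna_cursor + mod.n_mrna_members)
        lnc_cursor += mod.n_lnc_members
        mrna_cursor += mod.n_mrna_members
        module_rows.append(np.concatenate([lrows, mrows]))
        module_meta.append((lrows, mrows))
    module_feature_idx = (
        np.concatenate(module_rows) if module_rows else np.array([], dtype=int)
    )
    non_module = np.setdiff1d(np.arange(n_feat), module_feature_idx)

    # per-feature patient-level biological variability, shared by the T and
    # NT sample of a patient (cancels in the paired test); module members'
    # patient-level biology is the latent factor instead
    if config.biological_sd > 0:
        u = rng.normal(0.0, config.biological_sd, size=(n_feat, n))
        u[module_feature_idx] = 0.0
        patient_index = np.repeat(np.arange(n), 2)
        X += u[:, patient_index]

    # background differential expression on non-module features
    n_bg = int(round(config.de_background_fraction * non_module.size))
    bg_idx = rng.choice(non_module, size=n_bg, replace=False) if n_bg else np.array([], dtype=int)
    bg_sign = rng.choice([1.0, -1.0], size=n_bg)
    for idx, s in zip(bg_idx, bg_sign):
        X[idx, is_tumor] += s * config.de_background_shift

    # planted modules
    de_direction: dict[str, str] = {}
    for idx, s in zip(bg_idx.tolist(), bg_sign.tolist()):
        de_direction[feature_ids[idx]] = "up" if s > 0 else "down"
    clinical_links: dict[str, dict] = {}
    latent: dict[str, dict] = {}
    phenotype_labels: dict[str, dict] = {g: {} for g in LINKABLE_GROUPS[:4]}
    risk = np.zeros(n)
    truth_modules = []
    for k, (mod, (lrows, mrows)) in enumerate(zip(config.modules, module_meta)):
        rows = np.concatenate([lrows, mrows])
        z = _standardized_latent(rng, is_tumor)
        b = module_loading(mod.target_r, config.feature_noise_sd)
        X[rows] += b * z[None, :]
        X[np.ix_(rows, tumor_cols)] += mod.tumor_shift
        z_tumor = z[tumor_cols]
        latent[str(k)] = {p: float(v) for p, v in zip(patients, z_tumor)}
        link_direction = None
        if mod.linked_group in LINKABLE_GROUPS[:4]:
            thr = np.quantile(z_tumor, config.poor_quantile)
            if mod.phenotype_effect >= 0:
                poor = z_tumor > thr
                link_direction = "up_in_poor"
            else:
                poor = z_tumor < thr
                link_direction = "down_in_poor"
            poor_cols = tumor_cols[poor]
            X[np.ix_(rows, poor_cols)] += mod.phenotype_effect
            phenotype_labels[mod.linked_group] = {
                p: ("poor" if q else "good") for p, q in zip(patients, poor)
            }
            clinical_links[mod.linked_group] = {
                "module": k,
                "direction": link_direction,
            }
        elif mod.linked_group == "survival":
            risk += mod.hazard_beta * z_tumor
            link_direction = "up_in_poor" if mod.hazard_beta > 0 else "down_in_poor"
            clinical_links["survival"] = {"module": k, "direction": link_direction}
        if mod.tumor_shift != 0.0:
            d = "up" if mod.tumor_shift > 0 else "down"
            for r_ in rows:
                de_direction[feature_ids[r_]] = d
        truth_modules.append(
            {
                "index": k,
                "lnc_members": [feature_ids[i] for i in lrows],
                "mrna_members": [feature_ids[i] for i in mrows],
                "target_r": mod.target_r,
                "loading": b,
                "tumor_shift": mod.tumor_shift,
                "linked_group": mod.linked_group,
                "phenotype_effect": mod.phenotype_effect,
                "hazard_beta": mod.hazard_beta,
                "link_direction": link_direction,
                "pathway_name": f"MODULE{k}_PATHWAY",
            }
        )

    # unlinked clinical groups get independent fifty-fifty labels
    for group in LINKABLE_GROUPS[:4]:
        if not phenotype_labels[group]:
            draw = rng.random(n) < 0.5
            phenotype_labels[group] = {
                p: ("poor" if q else "good") for p, q in zip(patients, draw)
            }

    clinical = _clinical_from_labels(rng, patients, phenotype_labels)

    # survival: exponential events, independent uniform censoring
    lam = config.baseline_hazard * np.exp(risk)
    t_event = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0.0:
        c_max = _censoring_horizon(config.censoring_rate) / config.baseline_hazard
        c_time = rng.uniform(0.0, c_max, size=n)
        os_time = np.maximum(np.minimum(t_event, c_time), 1e-3)
        os_event = t_event <= c_time
    else:
        os_time = np.maximum(t_event, 1e-3)
        os_event = np.ones(n, dtype=bool)
    cens_draw = ~os_event
    clinical["os_time"] = np.round(os_time, 4)
    clinical["os_event"] = os_event

    # detection flags
    flags_arr = np.full((n_feat, n_samp), "Present", dtype=object)
    if config.flag_absent_quantile > 0.0:
        thr = np.quantile(X, config.flag_absent_quantile)
        flags_arr[X < thr] = "Absent"
    values = pd.DataFrame(np.round(X, 6), index=feature_ids, columns=sample_ids)
    flags = pd.DataFrame(flags_arr, index=feature_ids, columns=sample_ids)
    expression = ExpressionMatrix(values, flags)

    annotation = _make_annotation(feature_ids, set(lnc_ids), truth_modules)
    gene_sets = _make_gene_sets(rng, mrna_ids, truth_modules)

    truth = TruthRecord(
        modules=truth_modules,
        de_direction=de_direction,
        clinical_links=clinical_links,
        latent=latent,
        phenotype_labels=phenotype_labels,
        censored={p: bool(c) for p, c in zip(patients, cens_draw)},
    )
    return SimCohort(expression, design, clinical, annotation, gene_sets, truth)


def _censoring_horizon(rate: float) -> float:
    """Dimensionless horizon x = lambda0 * c_max with censored fraction
    (1 - exp(-x)) / x = rate for a unit-hazard exponential event time."""
    from scipy.optimize import brentq

    return float(brentq(lambda x: (1.0 - math.exp(-x)) / x - rate, 1e-9, 1e4))


def _clinical_from_labels(rng, patients, labels) -> pd.DataFrame:
    """Raw clinical fields consistent with the dichotomized group labels."""
    n = len(patients)
    tp = np.array([labels["tumor_properties"][p] == "poor" for p in patients])
    gr = np.array([labels["grade"][p] == "poor" for p in patients])
    cp = np.array([labels["capsule"][p] == "poor" for p in patients])
    iv = np.array([labels["invasion"][p] == "poor" for p in patients])
    # poor tumor-properties patients always breach the 5 cm size rule, so the
    # any-sub-phenotype-poor composite reproduces the planted label exactly
    size = np.where(tp, rng.uniform(5.0, 12.0, n), rng.uniform(1.5, 4.5, n))
    vascular = np.where(tp, rng.random(n) < 0.5, False)
    stage = np.where(
        tp,
        rng.integers(1, 5, size=n),
        rng.integers(1, 3, size=n),
    )
    grade = np.where(gr, rng.integers(3, 5, size=n), rng.integers(1, 3, size=n))
    encapsulation = np.where(
        cp,
        np.where(rng.random(n) < 0.5, "incomplete", "none"),
        "complete",
    )
    return pd.DataFrame(
        {
            "patient_id": patients,
            "tumor_size_cm": np.round(size, 2),
            "vascular_invasion": vascular.astype(bool),
            "stage": stage.astype(int),
            "grade": grade.astype(int),
            "encapsulation": encapsulation,
            "invasion": iv.astype(bool),
        }
    )


def _make_annotation(feature_ids, lnc_set, truth_modules) -> pd.DataFrame:
    """BED-style coordinates.

    The first lncRNA and first mRNA of every module sit adjacent on chr1
    (a guaranteed cis case, 1 Mb away from any other chr1 feature); every
    other feature is laid out round-robin over chr2..chr22 with 1 Mb
    spacing, so module members otherwise land on different chromosomes.
    """
    cis_lnc = {m["lnc_members"][0]: m["index"] for m in truth_modules}
    cis_mrna = {m["mrna_members"][0]: m["index"] for m in truth_modules}
    rows = []
    counters = {f"chr{c}": 0 for c in range(2, 23)}
    chroms = sorted(counters)
    rr = 0
    for fid in feature_ids:
        biotype = "lncRNA" if fid in lnc_set else "protein_coding"
        if fid in cis_lnc:
            base = (cis_lnc[fid] + 1) * 1_000_000
            rows.append((fid, biotype, "chr1", base, base + 1000, "+", fid))
        elif fid in cis_mrna:
            base = (cis_mrna[fid] + 1) * 1_000_000
            rows.append((fid, biotype, "chr1", base + 5000, base + 6000, "+", fid))
        else:
            chrom = chroms[rr % len(chroms)]
            rr += 1
            counters[chrom] += 1
            start = counters[chrom] * 1_000_000
            rows.append((fid, biotype, chrom, start, start + 1000, "+", fid))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "biotype", "chrom", "start", "end", "strand", "symbol"],
    )


def _make_gene_sets(rng, mrna_ids, truth_modules) -> dict:
    """One pathway per module (exactly its mRNA members) plus decoy sets."""
    sets = {}
    for m in truth_modules:
        sets[m["pathway_name"]] = list(m["mrna_members"])
    size = min(DECOY_SET_SIZE, len(mrna_ids))
    for d in range(N_DECOY_SETS):
        members = rng.choice(mrna_ids, size=size, replace=False)
        sets[f"DECOY_{d + 1:02d}"] = sorted(members.tolist())
    return sets


def write_cohort(cohort: SimCohort, outdir) -> dict:
    """Write every cohort artifact to ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "flags": os.path.join(outdir, "flags.tsv"),
        "design": os.path.join(outdir, "design.tsv"),
        "clinical": os.path.join(outdir, "clinical.tsv"),
        "annotation": os.path.join(outdir, "annotation.bed"),
        "gene_sets": os.path.join(outdir, "gene_sets.gmt"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_expression(cohort.expression, paths["expression"], flags_path=paths["flags"])
    write_design(cohort.design, paths["design"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_bed(cohort.annotation, paths["annotation"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    cohort.truth.to_json(paths["truth"])
    return paths
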