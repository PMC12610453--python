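"""Synthetic Ct panels, metadata and small snapshot fixtures.

The generator reproduces the statistical structure the inference assumes:
Gaussian noise on the delta-Ct scale with configurable dispersion, low-variance
housekeeping references, planted group effects on the log2 fold-regulation
scale, and clinical covariates that are independent of expression unless a
confounding knob is turned on. All randomness flows from one seeded generator,
so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from mirpanel.panel_io import (
    ROLE_CONTROL,
    ROLE_HOUSEKEEPING,
    ROLE_TARGET,
    DEFAULT_LOD_CT,
    CtTable,
    PanelLayout,
    SampleMeta,
)

CONTRAST_CANCER = "cancer_vs_healthy"
CONTRAST_POLE = "pole_vs_wildtype"

STUDY_HOUSEKEEPING = ("SNORD38B", "U6 snRNA", "SNORD49A")

# miRNAs with published relevance to endometrial cancer panels; used to give
# the default layout realistic names. The remainder are numbered placeholders.
_NAMED_TARGETS = (
    "hsa-miR-181a-5p",
    "hsa-miR-23a-3p",
    "hsa-miR-20b-5p",
    "hsa-miR-100-5p",
    "hsa-miR-200c-3p",
    "hsa-miR-125b-5p",
    "hsa-miR-149-3p",
    "hsa-miR-24-3p",
    "hsa-miR-27b-3p",
    "hsa-miR-23b-3p",
    "hsa-let-7a-5p",
    "hsa-let-7c-5p",
    "hsa-let-7d-5p",
    "hsa-let-7i-5p",
    "hsa-let-7f-5p",
    "hsa-let-7g-5p",
    "hsa-miR-26b-5p",
    "hsa-miR-26a-5p",
    "hsa-miR-19b-3p",
    "hsa-miR-191-5p",
    "hsa-miR-192-5p",
    "hsa-miR-10b-5p",
    "hsa-miR-10a-5p",
    "hsa-miR-34a-5p",
    "hsa-miR-200b-3p",
    "hsa-miR-15a-5p",
    "hsa-miR-205-5p",
    "hsa-miR-221-3p",
    "hsa-miR-210-3p",
)

_GENE_POOL = (
    "TGFBR2", "RUNX1", "MYC", "MET", "EGFR", "E2F1", "AKT1", "TP53", "STAT3",
    "HIF1A", "VEGFA", "RB1", "NRAS", "IL6", "CDK6", "CCNE1", "CASP3", "EZH2",
    "HMGA2", "FOXO1", "E2F3", "DNMT3B", "CREB1", "CCNE2", "CCND2", "ATM",
    "ZEB1", "MCL1", "IGF1R", "CCND1", "PTEN", "NOTCH1", "DNMT3A", "BMI1",
    "BCL2", "KRAS", "CDKN1A", "MDM2", "SMAD4", "CTNNB1",
)


def make_layout(
    n_targets: int = 84,
    n_controls: int = 9,
    lod_ct: float = DEFAULT_LOD_CT,
) -> PanelLayout:
    """Default 96-well style layout: targets, 3 housekeeping wells, controls."""
    targets = list(_NAMED_TARGETS[:n_targets])
    targets += [f"hsa-miR-sim-{i:02d}" for i in range(1, n_targets - len(targets) + 1)]
    assay_ids = tuple(targets) + STUDY_HOUSEKEEPING + tuple(
        f"ctrl-{i:02d}" for i in range(1, n_controls + 1)
    )
    roles = (
        (ROLE_TARGET,) * n_targets
        + (ROLE_HOUSEKEEPING,) * len(STUDY_HOUSEKEEPING)
        + (ROLE_CONTROL,) * n_controls
    )
    return PanelLayout(assay_ids, roles, lod_ct=lod_ct)


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect for one target assay.

    ``log2_effect`` is on the fold-regulation scale: positive means the assay
    is up-regulated in the first-named group of the contrast, i.e. the group's
    mean delta-Ct is shifted down by ``log2_effect`` cycles.
    """

    assay_id: str
    contrast: str = CONTRAST_CANCER
    log2_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.contrast not in (CONTRAST_CANCER, CONTRAST_POLE):
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated study-shaped panel run."""

    n_cancer: int = 40
    n_healthy: int = 20
    n_pole_mutant: int = 7
    n_target_assays: int = 84
    dct_sd: float = 1.8
    hk_mean_ct: float = 20.0
    hk_ct_sd: float = 0.25
    baseline_dct_range: tuple[float, float] = (1.0, 6.0)
    effects: tuple[EffectSpec, ...] = ()
    # Confounding knob: shift cancer BMI and couple BMI into delta-Ct.
    bmi_group_shift: float = 0.0
    bmi_dct_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pole_mutant > self.n_cancer:
            raise ValueError("n_pole_mutant cannot exceed n_cancer")
        if self.dct_sd <= 0:
            raise ValueError("dct_sd must be positive")
        if min(self.n_cancer, self.n_healthy) < 2:
            raise ValueError("each group needs at least 2 samples")
        lo, hi = self.baseline_dct_range
        if not lo <= hi:
            raise ValueError("baseline_dct_range must be (lo, hi) with lo <= hi")
        object.__setattr__(self, "effects", tuple(self.effects))

    def with_effects(self, effects: Sequence[EffectSpec]) -> "SimConfig":
        return replace(self, effects=tuple(effects))


def default_study_config(seed: int = 0, effects: Sequence[EffectSpec] = ()) -> SimConfig:
    """Study-shaped default: 40/20 groups, 7 POLE mutants, 84 targets, SD 1.8.

    The housekeeping level and baseline range keep every simulated Ct safely
    below the 35-cycle LOD, so missingness is 0% as in the emulated design.
    """
    return SimConfig(seed=seed, effects=tuple(effects))


def simulate_panel(
    config: SimConfig, layout: PanelLayout | None = None
) -> tuple[CtTable, list[SampleMeta]]:
    """Draw one panel of Ct values plus matching sample metadata.

    Model: per-assay baseline delta-Ct (uniform over ``baseline_dct_range``),
    additive Gaussian noise with SD ``dct_sd``, group-mean shifts of
    ``-log2_effect`` for effect-bearing assays, and reconstruction
    Ct = delta-Ct + per-sample housekeeping mean so normalization recovers the
    simulated delta-Ct exactly. POLE effects apply only within cancer samples.
    """
    if layout is None:
        layout = make_layout(n_targets=config.n_target_assays)
    targets = layout.target_assays
    if len(targets) != config.n_target_assays:
        raise ValueError(
            f"layout has {len(targets)} target assays, config expects "
            f"{config.n_target_assays}"
        )
    unknown = [e.assay_id for e in config.effects if e.assay_id not in targets]
    if unknown:
        raise ValueError(f"effects reference unknown target assays: {unknown}")

    rng = np.random.default_rng(config.seed)
    cancer_ids = [f"C{i:02d}" for i in range(1, config.n_cancer + 1)]
    healthy_ids = [f"H{i:02d}" for i in range(1, config.n_healthy + 1)]
    sample_ids = cancer_ids + healthy_ids
    n = len(sample_ids)
    is_cancer = np.array([s in set(cancer_ids) for s in sample_ids])

    mutants = set(
        rng.choice(cancer_ids, size=config.n_pole_mutant, replace=False).tolist()
    )
    is_mutant = np.array([s in mutants for s in sample_ids])

    # Housekeeping block: tight around hk_mean_ct; per-sample mean defines the
    # normalizer each target Ct is reconstructed against.
    n_hk = len(layout.housekeeping_assays)
    hk_ct = rng.normal(config.hk_mean_ct, config.hk_ct_sd, size=(n, n_hk))
    hk_mean = hk_ct.mean(axis=1)

    lo, hi = config.baseline_dct_range
    baseline = rng.uniform(lo, hi, size=len(targets))
    dct = baseline[None, :] + rng.normal(0.0, config.dct_sd, size=(n, len(targets)))

    # Covariates; independent of delta-Ct unless the confounding knob is on.
    age = np.clip(rng.normal(58.0, 9.0, size=n), 30.0, 88.0)
    bmi = np.clip(rng.normal(28.0, 4.5, size=n), 17.0, 45.0)
    if config.bmi_group_shift:
        bmi = bmi + config.bmi_group_shift * is_cancer
    if config.bmi_dct_slope:
        dct = dct + config.bmi_dct_slope * (bmi - bmi.mean())[:, None]
    grades = rng.choice(["G1", "G2", "G3"], size=n)

    col = {a: j for j, a in enumerate(targets)}
    for eff in config.effects:
        j = col[eff.assay_id]
        if eff.contrast == CONTRAST_CANCER:
            mask = is_cancer
        else:
            mask = is_mutant  # POLE effects never touch healthy samples
        dct[mask, j] -= eff.log2_effect

    ct = np.empty((n, len(layout.assay_ids)))
    jt = [layout.assay_ids.index(a) for a in targets]
    jh = [layout.assay_ids.index(a) for a in layout.housekeeping_assays]
    jc = [layout.assay_ids.index(a) for a in layout.control_assays]
    ct[:, jt] = dct + hk_mean[:, None]
    ct[:, jh] = hk_ct
    ct[:, jc] = rng.normal(25.0, 0.5, size=(n, len(jc)))

    meta = []
    for i, sid in enumerate(sample_ids):
        if is_cancer[i]:
            status = "mutant" if is_mutant[i] else "wildtype"
            grade = str(grades[i])
        else:
            status, grade = "not_applicable", None
        meta.append(
            SampleMeta(
                sample_id=sid,
                group="cancer" if is_cancer[i] else "healthy",
                pole_status=status,
                age=float(np.round(age[i], 1)),
                bmi=float(np.round(bmi[i], 1)),
                grade=grade,
            )
        )
    return CtTable(tuple(sample_ids), layout, ct), meta


# ---------------------------------------------------------------------------
# Snapshot fixtures: small local stand-ins for interaction / term / external
# differential-expression tables.
# ---------------------------------------------------------------------------

def make_interaction_snapshot(
    mirnas: Sequence[str],
    seed: int = 0,
    gene_pool: Sequence[str] = _GENE_POOL,
    mean_targets: int = 8,
    functional_frac: float = 0.7,
    weak_frac: float = 0.15,
) -> pd.DataFrame:
    """Random validated-interaction table (mirna, gene_symbol, support_type, source)."""
    rng = np.random.default_rng(seed)
    rows = []
    sources = ("mirtarbase", "tarbase", "mirecords")
    for mirna in mirnas:
        k = min(len(gene_pool), 1 + rng.poisson(mean_targets))
        genes = rng.choice(gene_pool, size=k, replace=False)
        for g in genes:
            u = rng.random()
            if u < functional_frac:
                support = "Functional MTI"
            elif u < functional_frac + weak_frac:
                support = "Functional MTI (Weak)"
            else:
                support = "Non-Functional MTI"
            rows.append((mirna, str(g), support, str(rng.choice(sources))))
    return pd.DataFrame(rows, columns=["mirna", "gene_symbol", "support_type", "source"])


def make_term_map(
    genes: Sequence[str],
    seed: int = 0,
    n_terms: int = 15,
    mean_term_size: int = 8,
) -> pd.DataFrame:
    """Random gene -> term mapping (term_id, term_name, gene_symbol)."""
    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(genes))
    rows = []
    for t in range(1, n_terms + 1):
        k = min(len(genes), max(2, rng.poisson(mean_term_size)))
        members = rng.choice(genes, size=k, replace=False)
        for g in members:
            rows.append((f"T{t:04d}", f"process_{t:02d}", str(g)))
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_symbol"])


def make_external_de_table(
    panel_de: pd.DataFrame,
    seed: int = 0,
    overlap_frac: float = 0.8,
    agreement: float = 0.8,
    arm_strip_frac: float = 0.2,
    lfc_noise_sd: float = 0.8,
) -> pd.DataFrame:
    """Synthetic sequencing-side DE table (mirna, log2fc, fdr).

    A configurable fraction of panel miRNAs overlaps; overlapping entries agree
    in sign with probability ``agreement``; a fraction of names has the arm
    suffix stripped to exercise stem matching.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in panel_de.iterrows():
        if rng.random() > overlap_frac:
            continue
        name = str(rec["mirna"])
        if rng.random() < arm_strip_frac and (
            name.endswith("-5p") or name.endswith("-3p")
        ):
            name = name[:-3]
        panel_lfc = float(rec["log2_fold_reg"])
        sign = np.sign(panel_lfc) if panel_lfc != 0 else rng.choice([-1.0, 1.0])
        if rng.random() > agreement:
            sign = -sign
        magnitude = abs(panel_lfc) * rng.uniform(0.4, 1.6) + abs(
            rng.normal(0.0, lfc_noise_sd)
        )
        rows.append((name, float(sign * max(magnitude, 0.05)), float(rng.uniform(0, 0.2))))
    return pd.DataFrame(rows, columns=["mirna", "log2fc", "fdr"])
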