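"""The multi-stage gene-switch screening pipeline.

Stages, mirroring a genome-scale screen for condition-specific bistable
genes:

1. **Rank** every gene by its bimodality score (delta_AIC) and keep the
   top fraction (default 10%).
2. **Screen** the candidates by the conditional separation D between the
   target-phenotype samples and all others; D > 1.8 flags a distinct
   target-specific expression state.
3. **Validate** survivors on an independent paired dataset: refit the
   two-component mixture on the validation samples, assign ON/OFF modes,
   and require the ON-mode occupancy to differ between tumor and normal
   groups (two-sided Fisher exact test, Benjamini-Hochberg adjusted).
4. **Classify** validated switches: *type 1* genes are bimodal within the
   target samples themselves (both modes hold at least a minor-mode
   fraction); *type 2* genes sit almost entirely in one mode in the
   target group with the remaining samples predominantly in the opposite
   mode.

A mode-enrichment operation asks, for an already-fitted bimodal gene,
whether one of its modes is over-represented in a category of conditions
(one-sided hypergeometric test with BH correction) — the way a
galactose-utilization switch shows up as one mode enriched for
"extra carbon source" conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix
from .mixture import BimodalityResult, delta_aic, separation_D, score_matrix

__all__ = [
    "ScreenConfig",
    "SwitchCall",
    "EnrichmentResult",
    "screen",
    "validate",
    "classify_type",
    "mode_enrichment",
    "run_pipeline",
    "calls_to_frame",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screening/classification pipeline."""

    target_label: str
    top_fraction: float = 0.10
    d_min: float = 1.8
    type1_minor_mode_min: float = 0.15
    type2_on_fraction_min: float = 0.90
    enrichment_alpha: float = 0.05
    multiple_testing: str = "bh"

    def __post_init__(self) -> None:
        for name in ("top_fraction", "type1_minor_mode_min", "type2_on_fraction_min", "enrichment_alpha"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {value}")
        if self.d_min <= 0:
            raise ValidationError(f"d_min must be positive, got {self.d_min}")
        if self.multiple_testing != "bh":
            raise ValidationError("only Benjamini-Hochberg ('bh') adjustment is supported")


@dataclass(frozen=True)
class SwitchCall:
    """Per-gene screening verdict."""

    gene_id: str
    delta_aic_rank: int
    D: float
    passed_screen: bool
    validated: bool = False
    validation_reason: str = ""
    validation_p: float = float("nan")
    validation_adjusted_p: float = float("nan")
    switch_type: str = "none"
    on_fraction_target: float = float("nan")
    on_fraction_other: float = float("nan")


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of a condition category within one mode."""

    gene_id: str
    category: str
    mode: str
    overlap: int
    expected: float
    p_value: float
    adjusted_p: float = float("nan")


def calls_to_frame(calls: list[SwitchCall]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(c) for c in calls])
    return frame.rename(columns={"delta_aic_rank": "rank"})


def _phenotype_mask(matrix: ExpressionMatrix, annotations: pd.DataFrame, target_label: str) -> np.ndarray:
    missing = [s for s in matrix.sample_ids if s not in annotations.index]
    if missing:
        raise ValidationError(f"annotations missing {len(missing)} sample(s), e.g. {missing[:3]}")
    if "phenotype" not in annotations.columns:
        raise ValidationError("annotation table needs a 'phenotype' column")
    pheno = annotations.loc[matrix.sample_ids, "phenotype"].to_numpy()
    mask = pheno == target_label
    if mask.sum() < 2:
        raise ValidationError(
            f"target phenotype {target_label!r} has {int(mask.sum())} sample(s); need >= 2"
        )
    if (~mask).sum() < 2:
        raise ValidationError("need >= 2 non-target samples")
    return mask


def screen(
    scores: pd.DataFrame,
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    config: ScreenConfig,
) -> list[SwitchCall]:
    """Top-fraction delta_AIC cut followed by the separation-D screen.

    The candidate pool is the top ``ceil(top_fraction * G)`` scoreable
    genes by delta_AIC (ties broken by gene_id); each candidate's D is
    computed for target-phenotype samples against all others and
    ``passed_screen`` flags D > d_min.
    """
    mask = _phenotype_mask(matrix, annotations, config.target_label)
    ranked = scores[scores["delta_aic"].notna()].sort_values(
        ["delta_aic", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    if ranked.empty:
        raise ValidationError("no scoreable genes in the scores table")
    n_top = int(math.ceil(config.top_fraction * len(ranked)))
    calls = []
    for rank, gene in enumerate(ranked["gene_id"].head(n_top), start=1):
        if gene not in matrix.data.index:
            raise ValidationError(f"scored gene {gene!r} is absent from the matrix")
        values = matrix.gene_values(gene)
        sep = separation_D(values, mask, gene_id=gene, target_label=config.target_label)
        calls.append(
            SwitchCall(
                gene_id=gene,
                delta_aic_rank=rank,
                D=sep.D,
                passed_screen=sep.D > config.d_min,
            )
        )
    return calls


def validate(
    calls: list[SwitchCall],
    validation_matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
    config: ScreenConfig,
    seed: int = 0,
) -> list[SwitchCall]:
    """Independent-dataset validation of screened genes.

    For each gene that passed the screen: fit the two-component mixture on
    the pooled validation samples (tumor + normal), assign each sample a
    mode by posterior responsibility, and test the 2x2 mode-by-group table
    with a two-sided Fisher exact test; BH-adjusted p < enrichment_alpha
    marks the gene validated.  Genes absent from the validation matrix are
    marked not validated with reason "absent".
    """
    for col in ("pair_id", "tumor_sample", "normal_sample"):
        if col not in pairs.columns:
            raise ValidationError(f"pairs table missing column {col!r}")
    tumor = [s for s in pairs["tumor_sample"] if s in validation_matrix.sample_ids]
    normal = [s for s in pairs["normal_sample"] if s in validation_matrix.sample_ids]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError("validation matrix must contain >= 2 tumor and >= 2 normal samples")
    shared = set(validation_matrix.gene_ids)
    candidates = [c for c in calls if c.passed_screen]
    if candidates and not any(c.gene_id in shared for c in candidates):
        raise ValidationError("no screened gene is present in the validation matrix")

    sample_order = tumor + normal
    is_tumor = np.array([True] * len(tumor) + [False] * len(normal))
    tested: list[tuple[int, float]] = []
    updated = {c.gene_id: c for c in calls}
    for call in candidates:
        if call.gene_id not in shared:
            updated[call.gene_id] = replace(
                call, validated=False, validation_reason="absent"
            )
            continue
        values = validation_matrix.data.loc[call.gene_id, sample_order].to_numpy(dtype=float)
        keep = np.isfinite(values)
        try:
            res = delta_aic(values[keep], gene_id=call.gene_id, rng=seed)
        except ValidationError as err:
            updated[call.gene_id] = replace(
                call, validated=False, validation_reason=f"unfittable: {err}"
            )
            continue
        high = res.high_mode
        grp = is_tumor[keep]
        table = [
            [int((high & grp).sum()), int((high & ~grp).sum())],
            [int((~high & grp).sum()), int((~high & ~grp).sum())],
        ]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        tested.append((call.gene_id, p))
    if tested:
        adj = stats.false_discovery_control([p for _, p in tested], method="bh")
        for (gene, p), q in zip(tested, adj):
            ok = q < config.enrichment_alpha
            updated[gene] = replace(
                updated[gene],
                validated=bool(ok),
                validation_reason="" if ok else "mode occupancy not different",
                validation_p=p,
                validation_adjusted_p=float(q),
            )
    return [updated[c.gene_id] for c in calls]


def classify_type(
    call: SwitchCall,
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    config: ScreenConfig,
    seed: int = 0,
) -> SwitchCall:
    """Assign type 1 / type 2 / none from the global mode occupancies.

    Using the two-component fit of the *global* profile: let f be the
    fraction of target samples in the high mode.  Type 1 requires both
    modes to each hold at least ``type1_minor_mode_min`` of the target
    samples; type 2 requires at least ``type2_on_fraction_min`` of target
    samples in one mode *and* the non-target samples predominantly in the
    opposite mode.  The two rules are mutually exclusive.
    """
    if not (call.passed_screen and call.validated):
        return replace(call, switch_type="none")
    mask = _phenotype_mask(matrix, annotations, config.target_label)
    values = matrix.gene_values(call.gene_id)
    keep = np.isfinite(values)
    res = delta_aic(values[keep], gene_id=call.gene_id, rng=seed)
    high = res.high_mode
    grp = mask[keep]
    f_target = float(high[grp].mean())
    f_other = float(high[~grp].mean())
    minor = min(f_target, 1.0 - f_target)
    if minor >= config.type1_minor_mode_min:
        switch_type = "type1"
    elif (
        f_target >= config.type2_on_fraction_min
        and (1.0 - f_other) >= config.type2_on_fraction_min
    ) or (
        (1.0 - f_target) >= config.type2_on_fraction_min
        and f_other >= config.type2_on_fraction_min
    ):
        switch_type = "type2"
    else:
        switch_type = "none"
    return replace(
        call,
        switch_type=switch_type,
        on_fraction_target=f_target,
        on_fraction_other=f_other,
    )


def mode_enrichment(
    result: BimodalityResult,
    condition_categories,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of categories within each mode.

    For each (mode, category) pair: with N samples, a mode of size n and a
    category of size K, the p-value is the upper hypergeometric tail of
    the observed overlap.  BH adjustment is applied across all pairs
    tested for the gene.
    """
    categories = np.asarray(condition_categories)
    if categories.shape[0] != result.mode_assignment.shape[0]:
        raise ValidationError(
            "condition categories must align with the mode assignment "
            f"({categories.shape[0]} vs {result.mode_assignment.shape[0]} samples)"
        )
    n_total = categories.shape[0]
    results = []
    for mode in ("low", "high"):
        in_mode = result.mode_assignment == mode
        n_mode = int(in_mode.sum())
        for category in np.unique(categories):
            in_cat = categories == category
            k_cat = int(in_cat.sum())
            overlap = int((in_mode & in_cat).sum())
            p = float(stats.hypergeom.sf(overlap - 1, n_total, k_cat, n_mode))
            results.append(
                EnrichmentResult(
                    gene_id=result.gene_id,
                    category=str(category),
                    mode=mode,
                    overlap=overlap,
                    expected=n_mode * k_cat / n_total,
                    p_value=p,
                )
            )
    adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
    results = [replace(r, adjusted_p=float(q)) for r, q in zip(results, adj)]
    return sorted(results, key=lambda r: (r.adjusted_p, r.p_value, r.category, r.mode))


def run_pipeline(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame,
    config: ScreenConfig,
    validation_matrix: ExpressionMatrix | None = None,
    pairs: pd.DataFrame | None = None,
    seed: int = 0,
    scores: pd.DataFrame | None = None,
) -> tuple[list[SwitchCall], pd.DataFrame]:
    """Full screen -> validate -> classify pass; returns (calls, scores)."""
    if scores is None:
        scores = score_matrix(matrix, seed=seed)
    calls = screen(scores, matrix, annotations, config)
    if validation_matrix is not None and pairs is not None:
        calls = validate(calls, validation_matrix, pairs, config, seed=seed)
    calls = [classify_type(c, matrix, annotations, config, seed=seed) for c in calls]
    return calls, scores
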