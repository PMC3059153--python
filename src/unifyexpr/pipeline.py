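"""Gene-by-gene application of the factor model across a whole dataset.

Two modes mirror the two ways a gene is measured:

* gene-level — one summary row per platform (p = number of platforms, at
  least 3 required), producing a unified expression measure that is a
  weighted average of the platform summaries;
* probe-level — all probes for the gene across all platforms enter the model
  directly (p = total probe count), with a median loading reported per
  platform so platform behaviour remains visible.

Each fitted gene also gets deterministic QC flags: negative or small loadings
are usually symptoms of a platform measuring near background or with a small
dynamic range, so the flags are computed from the loadings together with the
raw (unstandardized) summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fa_core
from .fa_core import (
    DEFAULT_MAX_ITER,
    DEFAULT_PSI_FLOOR,
    DEFAULT_XTOL,
    FactorModel,
    StandardizedVectorSet,
)

__all__ = [
    "GeneQCThresholds",
    "UnifiedExpression",
    "SkippedGene",
    "check_min_probes",
    "unify_gene_level",
    "unify_probe_level",
    "qc_classify",
    "compare_gene_vs_probe",
]

ANNOTATION_COLUMNS = ("probe_id", "gene_id", "platform", "copies")


@dataclass(frozen=True)
class GeneQCThresholds:
    """Cutoffs for the per-gene QC flags.

    min_median_expression
        Minimum per-platform median raw (log2) expression for a gene to count
        as expressed above background.  Either one number for all platforms or
        a mapping platform -> cutoff (sparse two-color platforms report log
        ratios centred near 0, so their cutoff is typically 0).
    min_iqr
        Minimum per-platform inter-quartile range (log2 units) across samples;
        below it the covariance for that platform is unreliable.
    low_loading_cutoff / high_loading_cutoff
        Loadings below the low cutoff flag the gene; the high cutoff is the
        conventional "well-measured" mark used in reports.
    """

    min_median_expression: float | Mapping[str, float] = 4.0
    min_iqr: float = 0.5
    low_loading_cutoff: float = 0.3
    high_loading_cutoff: float = 0.8

    def expression_cutoff(self, platform: str) -> float:
        if isinstance(self.min_median_expression, Mapping):
            return float(self.min_median_expression.get(platform, 0.0))
        return float(self.min_median_expression)


@dataclass(frozen=True)
class UnifiedExpression:
    """Per-gene unified expression (Thomson scores) plus model QC."""

    gene_id: str
    sample_ids: tuple[str, ...]
    scores: np.ndarray
    input_ids: tuple[str, ...]       # platforms (gene-level) or probes
    platforms: tuple[str, ...]       # platform of each input
    loadings: np.ndarray
    uniquenesses: np.ndarray
    weights: np.ndarray
    heywood: bool
    converged: bool
    n_iter: int
    qc_flags: frozenset[str] = frozenset()
    per_platform_median_loading: Mapping[str, float] | None = None

    @property
    def scores_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.sample_ids), name=self.gene_id)


@dataclass(frozen=True)
class SkippedGene:
    gene_id: str
    reason: str


def _align_samples(summaries: Mapping[str, pd.DataFrame]) -> list[str]:
    """Common sample order across platforms; sample sets must agree exactly."""
    platforms = list(summaries)
    ref = list(summaries[platforms[0]].columns)
    ref_set = set(ref)
    for name in platforms[1:]:
        cols = set(summaries[name].columns)
        if cols != ref_set:
            missing = sorted(ref_set ^ cols)
            raise ValueError(
                f"sample IDs differ between platforms {platforms[0]!r} and "
                f"{name!r}: {missing}"
            )
    return ref


def qc_classify(
    loadings: np.ndarray,
    platforms: Sequence[str],
    raw_summaries: Mapping[str, np.ndarray],
    thresholds: GeneQCThresholds,
) -> frozenset[str]:
    """Deterministic QC flags for one gene.

    ``raw_summaries`` maps each platform to its raw (unstandardized, log2)
    values for the gene — one vector in gene-level mode, a probes x samples
    block in probe-level mode.  Flags:

    * ``negative_loading`` — any fitted loading < 0;
    * ``low_loading`` — any loading below ``low_loading_cutoff``;
    * ``low_expression`` — any platform median below its expression cutoff;
    * ``low_iqr`` — any platform IQR below ``min_iqr``.
    """
    flags: set[str] = set()
    lam = np.asarray(loadings, dtype=float)
    if np.any(lam < 0):
        flags.add("negative_loading")
    if np.any(lam < thresholds.low_loading_cutoff):
        flags.add("low_loading")
    for platform in dict.fromkeys(platforms):
        vals = np.asarray(raw_summaries[platform], dtype=float).ravel()
        if np.median(vals) < thresholds.expression_cutoff(platform):
            flags.add("low_expression")
        q75, q25 = np.percentile(vals, [75, 25])
        if q75 - q25 < thresholds.min_iqr:
            flags.add("low_iqr")
    return frozenset(flags)


def _fit_one(
    gene_id: str,
    raw_block: np.ndarray,
    input_ids: Sequence[str],
    platforms: Sequence[str],
    sample_ids: Sequence[str],
    raw_by_platform: Mapping[str, np.ndarray],
    thresholds: GeneQCThresholds,
    em_kwargs: dict,
    median_per_platform: bool,
) -> UnifiedExpression:
    data = fa_core.standardize(raw_block, input_ids, platforms)
    model = fa_core.fit_em(data, **em_kwargs)
    scores = fa_core.thomson_scores(model, data)
    flags = qc_classify(model.loadings, platforms, raw_by_platform, thresholds)
    med = None
    if median_per_platform:
        lam = pd.Series(model.loadings, index=list(platforms))
        med = {k: float(v) for k, v in lam.groupby(level=0).median().items()}
    return UnifiedExpression(
        gene_id=gene_id,
        sample_ids=tuple(sample_ids),
        scores=scores.scores,
        input_ids=tuple(input_ids),
        platforms=tuple(platforms),
        loadings=model.loadings,
        uniquenesses=model.uniquenesses,
        weights=scores.weights,
        heywood=bool(model.heywood.any()),
        converged=model.converged,
        n_iter=model.n_iter,
        qc_flags=flags,
        per_platform_median_loading=med,
    )


def unify_gene_level(
    summaries: Mapping[str, pd.DataFrame],
    thresholds: GeneQCThresholds = GeneQCThresholds(),
    *,
    min_platforms: int = 3,
    xtol: float = DEFAULT_XTOL,
    max_iter: int = DEFAULT_MAX_ITER,
    psi_floor: float = DEFAULT_PSI_FLOOR,
) -> tuple[list[UnifiedExpression], list[SkippedGene]]:
    """Unified expression from per-platform gene summaries.

    ``summaries`` maps platform name -> genes x samples DataFrame of log2
    summaries.  Samples are aligned by ID (order may differ between files);
    a gene must be measured on at least ``min_platforms`` platforms (default
    3, the minimum for the single-factor model to be identified from the
    correlations alone).  Genes that cannot be fitted are returned in the
    skipped list with a reason, never silently dropped.
    """
    if not summaries:
        raise ValueError("no platform summaries given")
    sample_ids = _align_samples(summaries)
    mats = {name: df[sample_ids] for name, df in summaries.items()}
    n = len(sample_ids)

    all_genes: list[str] = []
    seen: set[str] = set()
    for df in mats.values():
        for g in df.index:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)

    em_kwargs = dict(xtol=xtol, max_iter=max_iter, psi_floor=psi_floor)
    results: list[UnifiedExpression] = []
    skipped: list[SkippedGene] = []
    for gene in all_genes:
        platforms = [name for name, df in mats.items() if gene in df.index]
        if len(platforms) < min_platforms:
            skipped.append(
                SkippedGene(gene, f"measured on {len(platforms)} platforms (< {min_platforms})")
            )
            continue
        if n <= len(platforms):
            skipped.append(SkippedGene(gene, "underdetermined: p >= n"))
            continue
        block = np.vstack([mats[name].loc[gene].to_numpy(dtype=float) for name in platforms])
        raw_by_platform = {name: block[i] for i, name in enumerate(platforms)}
        try:
            results.append(
                _fit_one(gene, block, platforms, platforms, sample_ids,
                         raw_by_platform, thresholds, em_kwargs, False)
            )
        except ValueError as exc:
            skipped.append(SkippedGene(gene, str(exc)))
    return results, skipped


def check_min_probes(
    annotation: pd.DataFrame,
    min_probes: Mapping[str, int],
    default_min: int = 5,
) -> pd.DataFrame:
    """Gene/platform pairs violating the minimum-probe rule of the probe sets.

    Gene-centric probe sets are conventionally required to contain at least 5
    matching probes on dense (Affymetrix-style) platforms and at least 3 on a
    sparser platform; ``min_probes`` maps platform -> minimum.  Returns a
    DataFrame (gene_id, platform, n_probes, required) of violations.
    """
    counts = annotation.groupby(["gene_id", "platform"]).size().rename("n_probes").reset_index()
    counts["required"] = counts["platform"].map(lambda pl: int(min_probes.get(pl, default_min)))
    return counts[counts["n_probes"] < counts["required"]].reset_index(drop=True)


def unify_probe_level(
    probes: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: GeneQCThresholds = GeneQCThresholds(),
    *,
    xtol: float = DEFAULT_XTOL,
    max_iter: int = DEFAULT_MAX_ITER,
    psi_floor: float = DEFAULT_PSI_FLOOR,
) -> tuple[list[UnifiedExpression], list[SkippedGene]]:
    """Unified expression fitted directly to probe measurements.

    ``probes`` is a probes x samples DataFrame (background-corrected,
    normalized, log2); ``annotation`` has columns probe_id, gene_id, platform
    (and optionally copies) with one row per probe row of the matrix.
    Replicate-spotted probes are distinct rows.  Each gene's model uses all of
    its probes jointly (p = total probes), so a per-platform median loading is
    reported as the platform-level summary of the fit.  Genes with fewer than
    2 usable probes or with p >= n are skipped with a reason; non-converged
    fits are returned flagged, not dropped.
    """
    for col in ("probe_id", "gene_id", "platform"):
        if col not in annotation.columns:
            raise ValueError(f"annotation is missing column {col!r}")
    missing = [p for p in annotation["probe_id"] if p not in probes.index]
    if missing:
        raise ValueError(f"annotation probes absent from matrix: {missing[:5]}")
    if annotation["probe_id"].duplicated().any():
        dup = annotation.loc[annotation["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe in annotation: {dup!r}")

    sample_ids = list(probes.columns)
    n = len(sample_ids)
    em_kwargs = dict(xtol=xtol, max_iter=max_iter, psi_floor=psi_floor)
    results: list[UnifiedExpression] = []
    skipped: list[SkippedGene] = []
    for gene, group in annotation.groupby("gene_id", sort=False):
        probe_ids = list(group["probe_id"])
        platforms = list(group["platform"])
        if len(probe_ids) < 2:
            skipped.append(SkippedGene(str(gene), "fewer than 2 probes"))
            continue
        if len(probe_ids) >= n:
            skipped.append(SkippedGene(str(gene), "underdetermined: p >= n"))
            continue
        block = probes.loc[probe_ids].to_numpy(dtype=float)
        raw_by_platform = {
            pl: block[[i for i, q in enumerate(platforms) if q == pl]]
            for pl in dict.fromkeys(platforms)
        }
        try:
            results.append(
                _fit_one(str(gene), block, probe_ids, platforms, sample_ids,
                         raw_by_platform, thresholds, em_kwargs, True)
            )
        except ValueError as exc:
            skipped.append(SkippedGene(str(gene), str(exc)))
    return results, skipped


def compare_gene_vs_probe(gene_ue: UnifiedExpression, probe_ue: UnifiedExpression) -> float:
    """Pearson correlation between gene-level and probe-level scores.

    The two score vectors are sign-aligned first (the factor sign is not
    identified, so anti-correlation is the same fit).  Returns NaN when either
    vector is constant, where the correlation is undefined.
    """
    if gene_ue.gene_id != probe_ue.gene_id:
        raise ValueError("scores belong to different genes")
    a = gene_ue.scores_series
    b = probe_ue.scores_series
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared samples")
    x, y = a[common].to_numpy(), b[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if float(x @ y) < 0:
        y = -y
    return float(np.corrcoef(x, y)[0, 1])
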