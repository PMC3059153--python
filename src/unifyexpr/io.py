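"""Tab-delimited I/O and deterministic fixture generation.

The interchange format throughout is plain TSV: expression matrices have a
header row of sample IDs and a first column of feature IDs; annotation and
design tables are simple column-named TSVs.  Writing defaults to full float
precision so a written matrix reads back bit-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import simulator
from .pipeline import ANNOTATION_COLUMNS, UnifiedExpression
from .evaluation import GroupDesign, ReplicateDesign

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "write_unified_tsv",
    "write_skipped_tsv",
    "read_probe_annotation",
    "read_replicate_design",
    "read_group_design",
    "read_truth_labels",
    "generate_fixtures",
]

# Replicate-set sizes of the fixture precision design (nine sets, one of size
# 4 and one of size 3, the rest pairs — a realistic tumor-bank shape).
FIXTURE_REPLICATE_SIZES = (2, 2, 4, 2, 3, 2, 2, 2, 2)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (first column IDs, header sample IDs).

    Rejects duplicate feature IDs, non-numeric or missing cells (naming the
    offending row and column) and ragged rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().any().any():
        i, j = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    # cell-wise float() parsing: correctly rounded, so full-precision writes
    # round-trip bit-identically (read_csv's fast parser can be off by 1 ulp)
    numeric = df.map(float)
    numeric.index.name = df.index.name or "feature_id"
    return numeric


def write_expression_tsv(
    values: pd.DataFrame, path: str | Path, float_format: str | None = None
) -> None:
    """Write a features x samples matrix as TSV.

    ``float_format=None`` writes full (round-trip) precision; pass e.g.
    ``"%.6g"`` for compact human-readable output.
    """
    values = values.copy()
    values.index.name = values.index.name or "feature_id"
    values.to_csv(path, sep="\t", float_format=float_format)


def write_unified_tsv(
    results: Sequence[UnifiedExpression],
    path: str | Path,
    float_format: str | None = None,
) -> tuple[Path, Path]:
    """Write unified scores (gene x sample TSV) plus a sibling QC table.

    The QC file (``<stem>.qc.tsv``) has one row per gene with columns:
    gene_id, n_inputs, inputs, platforms, loadings, uniquenesses, weights
    (comma-joined, one entry per input), median loading per platform,
    heywood, converged, n_iter, qc_flags.  Returns (scores_path, qc_path).
    """
    if not results:
        raise ValueError("no results to write")
    scores = pd.DataFrame(
        [r.scores for r in results],
        index=pd.Index([r.gene_id for r in results], name="gene_id"),
        columns=list(results[0].sample_ids),
    )
    path = Path(path)
    write_expression_tsv(scores, path, float_format=float_format)

    def join(v: np.ndarray) -> str:
        fmt = float_format or "%.17g"
        return ",".join(fmt % x for x in v)

    rows = []
    for r in results:
        med = r.per_platform_median_loading or {}
        rows.append(
            {
                "gene_id": r.gene_id,
                "n_inputs": len(r.input_ids),
                "inputs": ",".join(r.input_ids),
                "platforms": ",".join(r.platforms),
                "loadings": join(r.loadings),
                "uniquenesses": join(r.uniquenesses),
                "weights": join(r.weights),
                "median_loading_per_platform": ",".join(
                    f"{k}={v:.6g}" for k, v in sorted(med.items())
                ),
                "heywood": r.heywood,
                "converged": r.converged,
                "n_iter": r.n_iter,
                "qc_flags": ",".join(sorted(r.qc_flags)),
            }
        )
    qc_path = path.with_name(path.stem + ".qc.tsv")
    pd.DataFrame(rows).to_csv(qc_path, sep="\t", index=False)
    return path, qc_path


def write_skipped_tsv(skipped, path: str | Path) -> None:
    """Write the skipped-genes report (gene_id, reason)."""
    pd.DataFrame(
        [{"gene_id": s.gene_id, "reason": s.reason} for s in skipped],
        columns=["gene_id", "reason"],
    ).to_csv(path, sep="\t", index=False)


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, gene_id, platform[, copies])."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str, "platform": str})
    for col in ANNOTATION_COLUMNS[:3]:
        if col not in df.columns:
            raise ValueError(f"{path}: annotation is missing column {col!r}")
    if "copies" not in df.columns:
        df["copies"] = 1
    df["copies"] = df["copies"].astype(int)
    if (df["copies"] < 1).any():
        raise ValueError(f"{path}: copies must be >= 1")
    return df


def read_replicate_design(path: str | Path) -> ReplicateDesign:
    """Read a replicate design TSV with columns sample_id, replicate_set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "replicate_set"):
        if col not in df.columns:
            raise ValueError(f"{path}: replicate design is missing column {col!r}")
    groups = tuple(
        tuple(g["sample_id"]) for _, g in df.groupby("replicate_set", sort=True)
    )
    return ReplicateDesign(groups=groups)


def read_group_design(path: str | Path) -> GroupDesign:
    """Read a two-group design TSV with columns sample_id, group (1 or 2)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: group design is missing column {col!r}")
    g1 = tuple(df.loc[df["group"] == "1", "sample_id"])
    g2 = tuple(df.loc[df["group"] == "2", "sample_id"])
    return GroupDesign(group1=g1, group2=g2)


def read_truth_labels(path: str | Path) -> pd.Series:
    """Read truth labels TSV (gene_id, label in positive/negative/excluded)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: truth labels missing column {col!r}")
    bad = set(df["label"]) - {"positive", "negative", "excluded"}
    if bad:
        raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return df.set_index("gene_id")["label"]


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

_PLATFORMS = ("u133", "exon", "agilent")
# Probe counts per platform for the probe-rich fixture gene and the ordinary
# ones; the first mirrors a dense-platform-dominated gene (many dense-array
# probes against a 3-probe two-color platform).
_PROBE_RICH = (55, 11, 3)
_PROBE_PLAIN = (6, 5, 3)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(6)


def generate_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a deterministic synthetic dataset exercising every pipeline path.

    Produces, under ``outdir``:

    * ``platform_<name>.tsv`` x3 — gene-level log2 summaries (40 genes x 60
      samples) containing concordant, one-platform-discordant, near-null,
      Heywood-prone, low-expression and low-IQR genes;
    * ``probes.tsv`` + ``probe_annotation.tsv`` — probe-level data for 6
      genes, one with 55/11/3 probes per platform;
    * ``reference.tsv`` — a noisy standardized reference tracking the truth
      on a 31-sample subset;
    * ``truth.tsv`` — the latent factor values behind the gene-level data;
    * ``replicates.tsv`` — nine replicate sets with sizes (2,2,4,2,3,2,2,2,2);
    * ``groups.tsv`` — a two-group split of the reference samples (7 vs 24);
    * ``truth_labels.tsv`` — positive/negative/excluded labels from planted
      group shifts;
    * ``qc_thresholds.yaml`` — QC cutoffs matched to the fixture platforms.

    The same seed yields byte-identical files.  Returns name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = 60
    samples = [f"S{i:03d}" for i in range(n)]

    gene_plans: list[tuple[str, np.ndarray]] = []
    for i in range(20):  # concordant genes
        gene_plans.append((f"CONC{i:02d}", np.array([0.92, 0.90, 0.88])))
    for i in range(10):  # one discordant platform
        gene_plans.append((f"DISC{i:02d}", np.array([0.90, 0.90, 0.10])))
    for i in range(4):  # near-null genes
        gene_plans.append((f"NULL{i:02d}", np.array([0.15, 0.10, 0.05])))
    for i in range(4):  # Heywood-prone: one near-perfect platform
        gene_plans.append((f"HEYW{i:02d}", np.array([0.999, 0.60, 0.50])))
    gene_plans.append(("LOWEXPR00", np.array([0.85, 0.85, 0.85])))
    gene_plans.append(("LOWIQR00", np.array([0.85, 0.85, 0.85])))

    # Two-group structure for fold-change/ROC fixtures: first 7 of the
    # reference subset vs the remaining 24.
    ref_samples = samples[:31]
    group1, group2 = ref_samples[:7], ref_samples[7:31]

    truth_rows, labels = {}, {}
    per_platform: dict[str, dict[str, np.ndarray]] = {p: {} for p in _PLATFORMS}
    for gi, (gene, lam) in enumerate(gene_plans):
        y, f = simulator.simulate_from_loadings(lam, n, rng)
        if gi % 3 == 0:  # planted differential expression in group 1
            shift = np.zeros(n)
            shift[:7] = 1.5
            f = f + shift
            y = y + lam[:, None] * shift[None, :]
            labels[gene] = "positive"
        else:
            labels[gene] = "negative" if gi % 3 == 1 else "excluded"
        truth_rows[gene] = f
        baseline = 2.0 if gene.startswith("LOWEXPR") else 7.5
        scale = 0.05 if gene.startswith("LOWIQR") else 1.2
        for j, p in enumerate(_PLATFORMS):
            base = 0.0 if p == "agilent" else baseline  # two-color log ratios sit near 0
            per_platform[p][gene] = base + scale * y[j]

    # Replicate sets (samples 31..51): make members technical near-copies of
    # the first member so the precision statistics are meaningful.
    rep_members: list[list[int]] = []
    cursor = 31
    for size in FIXTURE_REPLICATE_SIZES:
        rep_members.append(list(range(cursor, cursor + size)))
        cursor += size

    paths: dict[str, Path] = {}
    for p in _PLATFORMS:
        df = pd.DataFrame(per_platform[p], index=samples).T
        df.index.name = "gene_id"
        for members in rep_members:
            first = samples[members[0]]
            for m in members[1:]:
                df[samples[m]] = df[first] + 0.15 * rng.standard_normal(len(df))
        paths[f"platform_{p}"] = outdir / f"platform_{p}.tsv"
        _fmt(df).to_csv(paths[f"platform_{p}"], sep="\t")

    truth = pd.DataFrame(truth_rows, index=samples).T
    truth.index.name = "gene_id"
    paths["truth"] = outdir / "truth.tsv"
    _fmt(truth).to_csv(paths["truth"], sep="\t")

    # Probe-level block: per-probe loadings around a shared latent factor.
    probe_rows, ann_rows = {}, []
    probe_genes = ["PRB_RICH00"] + [f"PRB{i:02d}" for i in range(5)]
    for gi, gene in enumerate(probe_genes):
        counts = _PROBE_RICH if gene == "PRB_RICH00" else _PROBE_PLAIN
        f = rng.standard_normal(n)
        for p, cnt in zip(_PLATFORMS, counts):
            for k in range(cnt):
                lam_probe = rng.uniform(0.6, 0.95)
                e = rng.standard_normal(n) * np.sqrt(1 - lam_probe**2)
                pid = f"{gene}_{p}_{k:02d}"
                probe_rows[pid] = 7.5 + 1.1 * (lam_probe * f + e)
                ann_rows.append(
                    {"probe_id": pid, "gene_id": gene, "platform": p, "copies": 1}
                )
    probes = pd.DataFrame(probe_rows, index=samples).T
    probes.index.name = "probe_id"
    paths["probes"] = outdir / "probes.tsv"
    _fmt(probes).to_csv(paths["probes"], sep="\t")
    paths["probe_annotation"] = outdir / "probe_annotation.tsv"
    pd.DataFrame(ann_rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        paths["probe_annotation"], sep="\t", index=False
    )

    # Reference: truth on 31 samples plus noise, standardized per gene.
    ref = truth[ref_samples] + 0.6 * rng.standard_normal((len(truth), 31))
    ref = ref.sub(ref.mean(axis=1), axis=0).div(ref.std(axis=1, ddof=1), axis=0)
    paths["reference"] = outdir / "reference.tsv"
    _fmt(ref).to_csv(paths["reference"], sep="\t")

    rep_rows = []
    for si, members in enumerate(rep_members):
        for m in members:
            rep_rows.append({"sample_id": samples[m], "replicate_set": f"set{si:02d}"})
    paths["replicates"] = outdir / "replicates.tsv"
    pd.DataFrame(rep_rows).to_csv(paths["replicates"], sep="\t", index=False)

    paths["groups"] = outdir / "groups.tsv"
    pd.DataFrame(
        [{"sample_id": s, "group": "1"} for s in group1]
        + [{"sample_id": s, "group": "2"} for s in group2]
    ).to_csv(paths["groups"], sep="\t", index=False)

    paths["truth_labels"] = outdir / "truth_labels.tsv"
    pd.DataFrame(
        [{"gene_id": g, "label": lab} for g, lab in labels.items()]
    ).to_csv(paths["truth_labels"], sep="\t", index=False)

    # QC thresholds matched to the fixture platforms: the two-color log-ratio
    # platform sits near 0, so its expression cutoff is 0.
    paths["qc_thresholds"] = outdir / "qc_thresholds.yaml"
    paths["qc_thresholds"].write_text(
        "thresholds:\n"
        "  min_median_expression:\n"
        "    u133: 4.0\n"
        "    exon: 4.0\n"
        "    agilent: 0.0\n"
        "  min_iqr: 0.5\n"
        "  low_loading_cutoff: 0.3\n"
        "  high_loading_cutoff: 0.8\n"
    )
    return paths
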