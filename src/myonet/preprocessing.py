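"""Study-level preprocessing: probe collapsing, z-transformation, batch merging.

The analysis operates on one expression study per disease, each holding a
genes x samples matrix with a *disease* arm and a *control* arm.  Raw probe
level matrices are collapsed to gene level (MaxMean rule), genes are
standardized across all samples of a study, and multi-batch studies are
merged after per-batch gene-wise standardization (a simple, transparent
stand-in for empirical-Bayes batch correction, which is out of scope here).
All downstream statistics are location-shift based, so per-gene affine
rescaling does not change them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ARM_DISEASE = "disease"
ARM_CONTROL = "control"
_VALID_ARMS = (ARM_DISEASE, ARM_CONTROL)


@dataclass
class ExpressionStudy:
    """One disease's expression matrix with sample annotations.

    Parameters
    ----------
    disease_id : str
        Label of the disease this study profiles.
    gene_ids : list of str
        Row labels, unique after probe collapsing.
    values : ndarray, shape (n_genes, n_samples)
        Expression values on a post-normalization scale.
    sample_ids : list of str
        Column labels.
    arms : ndarray of str
        Per-sample arm, each ``"disease"`` or ``"control"``.
    batches : ndarray
        Per-sample batch identifier.
    constant_genes : frozenset of str
        Genes flagged as constant (zero variance) by :func:`ztransform`.
    """

    disease_id: str
    gene_ids: list
    values: np.ndarray
    sample_ids: list
    arms: np.ndarray
    batches: np.ndarray
    constant_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.arms = np.asarray(self.arms)
        self.batches = np.asarray(self.batches)
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match value rows")
        if len(self.sample_ids) != n_samples or len(self.arms) != n_samples:
            raise ValueError("sample annotations do not match value columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError(f"duplicate gene ids in study {self.disease_id!r}")
        bad = set(np.unique(self.arms)) - set(_VALID_ARMS)
        if bad:
            raise ValueError(f"unknown arm labels {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def arm_matrix(self, arm: str) -> np.ndarray:
        """Columns of ``values`` belonging to one arm."""
        if arm not in _VALID_ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        return self.values[:, self.arms == arm]

    def check_arms(self, min_per_arm: int = 2) -> None:
        for arm in _VALID_ARMS:
            n = int(np.sum(self.arms == arm))
            if n < min_per_arm:
                raise ValueError(
                    f"study {self.disease_id!r}: arm {arm!r} has {n} samples, "
                    f"needs at least {min_per_arm}"
                )


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples (MaxMean rule).

    For every gene measured by several probes the probe row with the highest
    mean value across samples is retained; ties are broken toward the
    lexicographically smallest probe id.  Probes absent from the mapping are
    dropped.  Output rows are ordered lexicographically by gene id.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    genes = pd.Series(
        [probe_to_gene.get(p) for p in matrix.index], index=matrix.index, dtype=object
    )
    mapped = genes.notna()
    if not mapped.any():
        raise ValueError("no probe in the matrix maps to a gene")
    sub = matrix.loc[mapped]
    means = sub.mean(axis=1)
    pick = (
        pd.DataFrame(
            {"gene": genes[mapped].values, "mean": means.values, "probe": sub.index}
        )
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    out = sub.loc[pick["probe"].values].copy()
    out.index = pick["gene"].values
    return out.sort_index()


def zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each row to mean 0, sample sd 1 (n-1 denominator).

    Returns the standardized matrix and a boolean mask of constant rows,
    which are mapped to all zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    safe = np.where(sd == 0.0, 1.0, sd)
    out = (values - mean) / safe
    out[constant] = 0.0
    return out, constant


def ztransform(study: ExpressionStudy) -> ExpressionStudy:
    """Per-gene z-transformation across all samples (both arms pooled).

    Constant genes become all-zero rows and are flagged in
    ``constant_genes``.  Idempotent: applying it twice gives the same study.
    """
    out, constant = zscore_rows(study.values)
    flagged = frozenset(g for g, c in zip(study.gene_ids, constant) if c)
    return replace(study, values=out, constant_genes=study.constant_genes | flagged)


def merge_batches(studies: list) -> ExpressionStudy:
    """Merge several studies/batches of one disease into a single study.

    Genes are restricted to the intersection across inputs; within every
    batch each gene row is standardized (mean 0, sd 1 across the batch's
    samples, arms pooled) before column-wise concatenation, which removes
    additive per-batch offsets.  Batch ids are preserved, prefixed with the
    input index to keep them unique.  Single-sample batches are centered
    only.
    """
    if not studies:
        raise ValueError("no studies to merge")
    ids = {s.disease_id for s in studies}
    if len(ids) != 1:
        raise ValueError(f"merge_batches expects one disease, got {sorted(ids)}")
    common = set(studies[0].gene_ids)
    for s in studies[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise ValueError("empty gene intersection across batches")
    universe = sorted(common)

    blocks, sample_ids, arms, batches = [], [], [], []
    for k, s in enumerate(studies):
        lookup = {g: i for i, g in enumerate(s.gene_ids)}
        rows = np.array([lookup[g] for g in universe])
        vals = s.values[rows]
        for b in np.unique(s.batches):
            cols = np.where(s.batches == b)[0]
            block = vals[:, cols]
            if block.shape[1] >= 2:
                block, _ = zscore_rows(block)
            else:
                block = block - block.mean(axis=1, keepdims=True)
            blocks.append(block)
            sample_ids.extend(s.sample_ids[c] for c in cols)
            arms.extend(s.arms[cols])
            batches.extend(f"{k}:{b}" for _ in cols)
    return ExpressionStudy(
        disease_id=studies[0].disease_id,
        gene_ids=universe,
        values=np.hstack(blocks),
        sample_ids=sample_ids,
        arms=np.array(arms),
        batches=np.array(batches),
    )


def intersect_genes(studies: list) -> tuple[list, list]:
    """Restrict all studies to their common gene universe.

    Returns the universe (lexicographic order) and the re-indexed studies.
    """
    if not studies:
        raise ValueError("no studies given")
    common = set(studies[0].gene_ids)
    for s in studies[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise ValueError("empty gene intersection across studies")
    universe = sorted(common)
    out = []
    for s in studies:
        lookup = {g: i for i, g in enumerate(s.gene_ids)}
        rows = np.array([lookup[g] for g in universe])
        out.append(replace(s, gene_ids=list(universe), values=s.values[rows]))
    return universe, out


# ---------------------------------------------------------------------------
# File readers (synthetic-data dialect plus a minimal series-matrix reader)

def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes/probes x samples TSV (first column = row ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, disease, arm, batch."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "disease", "arm", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    return df


def read_probe_map(path) -> dict:
    """Read a two-column TSV (probe_id, gene_symbol) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_study(expr_path, sheet_path, disease_id: str | None = None) -> ExpressionStudy:
    """Assemble an :class:`ExpressionStudy` from an expression TSV and sheet."""
    mat = read_expression_tsv(expr_path)
    sheet = read_sample_sheet(sheet_path)
    if disease_id is not None:
        sheet = sheet[sheet["disease"] == disease_id]
    diseases = sheet["disease"].unique()
    if len(diseases) != 1:
        raise ValueError(f"sample sheet covers {len(diseases)} diseases; pass disease_id")
    sheet = sheet.set_index("sample_id").loc[list(mat.columns)]
    return ExpressionStudy(
        disease_id=str(diseases[0]),
        gene_ids=list(mat.index),
        values=mat.values,
        sample_ids=list(mat.columns),
        arms=sheet["arm"].values,
        batches=sheet["batch"].values,
    )


def read_series_matrix(path) -> pd.DataFrame:
    """Minimal reader for the GEO "series matrix" text layout.

    Header lines prefixed with ``!`` are ignored; the expression table sits
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    """
    lines, in_table = [], False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if in_table and stripped:
                lines.append(line)
    if not lines:
        raise ValueError(f"no series-matrix table found in {path}")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    return df
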