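"""Core data containers and delimited-text I/O for multi-omics tables.

An :class:`OmicsMatrix` is one view's samples x features numeric matrix with
verbatim string identifiers. A :class:`MultiOmicsDataset` bundles several
views with optional survival and clinical tables; :func:`align_samples`
restricts everything to the shared sample set in a deterministic
(lexicographic) order. Preprocessing follows the standard expression /
methylation pipeline: drop features with missing values or an excessive
zero fraction, log2(x+1)-transform expression views, average duplicate
methylation probes mapping to the same gene, and drop zero-variance
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SurvivalTable",
    "ClinicalTable",
    "MultiOmicsDataset",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_survival_table",
    "read_clinical_table",
    "align_samples",
    "filter_expression_features",
    "log2_transform",
    "filter_variance",
]

_MISSING_MARKERS = {"", "NA", "NaN", "nan", "N/A", "null", "NULL"}


@dataclass
class OmicsMatrix:
    """One omics view: an N x d_v real matrix with sample/feature IDs."""

    view_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # N x d_v, may contain NaN before preprocessing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"view '{self.view_name}': values shape {self.values.shape} "
                f"does not match {len(self.sample_ids)} samples x "
                f"{len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"view '{self.view_name}': duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"view '{self.view_name}': duplicate feature IDs")
        if len(self.sample_ids) < 2:
            raise ValueError(f"view '{self.view_name}': need at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_samples(self, ids: list[str]) -> "OmicsMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return OmicsMatrix(self.view_name, list(ids),
                           list(self.feature_ids), self.values[idx])


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and binary event indicator (1 = event)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("survival table: duplicate sample IDs")
        if self.time.shape != (len(self.sample_ids),) or \
                self.event.shape != (len(self.sample_ids),):
            raise ValueError("survival table: column lengths disagree")
        if np.any(np.isnan(self.time)) or np.any(self.time < 0):
            raise ValueError("survival table: times must be nonnegative and complete")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("survival table: event must be 0/1")

    def subset_samples(self, ids: list[str]) -> "SurvivalTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return SurvivalTable(list(ids), self.time[idx], self.event[idx])


@dataclass
class ClinicalTable:
    """Named covariates per sample, each tagged categorical or numeric.

    Missing values are allowed (NaN for numeric, None for categorical) and
    are dropped per-test downstream, never imputed.
    """

    sample_ids: list[str]
    columns: pd.DataFrame  # index = sample_ids
    column_types: dict[str, str]  # name -> "categorical" | "numeric"

    def __post_init__(self):
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("clinical table: duplicate sample IDs")
        for name, tag in self.column_types.items():
            if tag not in ("categorical", "numeric"):
                raise ValueError(f"clinical column '{name}': unknown tag '{tag}'")
            if name not in self.columns.columns:
                raise ValueError(f"clinical column '{name}' tagged but absent")
            if tag == "numeric" and not pd.api.types.is_numeric_dtype(
                    self.columns[name]):
                raise ValueError(f"clinical column '{name}' tagged numeric "
                                 "but stored non-numeric")

    def missingness(self) -> dict[str, int]:
        return {c: int(self.columns[c].isna().sum()) for c in self.columns}

    def subset_samples(self, ids: list[str]) -> "ClinicalTable":
        return ClinicalTable(list(ids), self.columns.loc[ids],
                             dict(self.column_types))


@dataclass
class MultiOmicsDataset:
    views: list[OmicsMatrix]
    survival: SurvivalTable | None = None
    clinical: ClinicalTable | None = None

    @property
    def sample_ids(self) -> list[str]:
        return self.views[0].sample_ids

    @property
    def n_views(self) -> int:
        return len(self.views)


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_omics_matrix(path: str, view_name: str | None = None,
                      orientation: str = "samples-in-rows") -> OmicsMatrix:
    """Read a delimited matrix (header row + ID column) into an OmicsMatrix.

    ``orientation="features-in-rows"`` transposes, so the result is always
    samples-in-rows. Non-numeric body cells other than missing markers raise
    a parse error naming the offending row and column.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation '{orientation}'")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate IDs")
    body = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for j in range(df.shape[1]):
        for i in range(df.shape[0]):
            cell = raw[i, j].strip()
            if cell in _MISSING_MARKERS:
                body[i, j] = np.nan
                continue
            try:
                body[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value '{cell}' at row "
                    f"'{df.index[i]}', column '{df.columns[j]}'"
                ) from None
    if orientation == "features-in-rows":
        body = body.T
        samples, features = list(df.columns), list(df.index)
    else:
        samples, features = list(df.index), list(df.columns)
    name = view_name if view_name is not None else str(path)
    return OmicsMatrix(name, [str(s) for s in samples],
                       [str(f) for f in features], body)


def write_omics_matrix(m: OmicsMatrix, path: str, sep: str = "\t") -> None:
    df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids)
    # repr-based float formatting round-trips float64 exactly
    df.to_csv(path, sep=sep, float_format=None)


def read_survival_table(path: str) -> SurvivalTable:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: survival table needs columns {sorted(required)}")
    return SurvivalTable([str(s) for s in df["sample"]],
                         df["time"].to_numpy(), df["event"].to_numpy())


def read_clinical_table(path: str, column_types: dict[str, str]) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "sample" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a 'sample' column")
    ids = [str(s) for s in df["sample"]]
    cols = df.drop(columns=["sample"])
    cols.index = ids
    for name, tag in column_types.items():
        if tag == "numeric":
            cols[name] = pd.to_numeric(cols[name], errors="coerce")
        else:
            cols[name] = cols[name].where(
                ~cols[name].astype(str).str.strip().isin(_MISSING_MARKERS))
    return ClinicalTable(ids, cols, column_types)


def align_samples(dataset: MultiOmicsDataset) -> MultiOmicsDataset:
    """Restrict all views/tables to the shared samples, lexicographic order.

    Samples lacking survival information are excluded whenever a survival
    table is present. Idempotent; raises on an empty intersection.
    """
    if not dataset.views:
        raise ValueError("dataset has no views")
    common = set(dataset.views[0].sample_ids)
    for v in dataset.views[1:]:
        common &= set(v.sample_ids)
    if dataset.survival is not None:
        common &= set(dataset.survival.sample_ids)
    if not common:
        raise ValueError("no samples shared across all views/tables")
    order = sorted(common)
    views = [v.subset_samples(order) for v in dataset.views]
    survival = (dataset.survival.subset_samples(order)
                if dataset.survival is not None else None)
    clinical = None
    if dataset.clinical is not None:
        keep = [s for s in order if s in set(dataset.clinical.sample_ids)]
        if keep != order:
            # clinical rows are optional per sample: keep alignment but allow
            # missing rows as all-NaN entries
            cols = dataset.clinical.columns.reindex(order)
            clinical = ClinicalTable(order, cols,
                                     dict(dataset.clinical.column_types))
        else:
            clinical = dataset.clinical.subset_samples(order)
    return MultiOmicsDataset(views, survival, clinical)


def filter_expression_features(m: OmicsMatrix,
                               max_zero_fraction: float = 0.30) -> OmicsMatrix:
    """Expression-view feature filter.

    Drops any feature with at least one missing value or with a zero
    fraction strictly above ``max_zero_fraction`` (a feature exactly at the
    boundary is kept), then drops zero-variance features. Feature order is
    preserved.
    """
    vals = m.values
    has_missing = np.isnan(vals).any(axis=0)
    zero_frac = np.mean(vals == 0.0, axis=0, where=~np.isnan(vals))
    zero_frac = np.nan_to_num(zero_frac, nan=1.0)
    keep = ~has_missing & (zero_frac <= max_zero_fraction)
    kept = vals[:, keep]
    nonconst = kept.std(axis=0) > 0
    keep_idx = np.flatnonzero(keep)[nonconst]
    if keep_idx.size == 0:
        raise ValueError(f"view '{m.view_name}': all features filtered out")
    return OmicsMatrix(m.view_name, list(m.sample_ids),
                       [m.feature_ids[i] for i in keep_idx],
                       vals[:, keep_idx])


def log2_transform(m: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """Elementwise log2(x + pseudocount); requires nonnegative input."""
    if np.nanmin(m.values) < 0:
        raise ValueError(f"view '{m.view_name}': negative values cannot be "
                         "log2-transformed")
    return replace(m, values=np.log2(m.values + pseudocount))


def filter_variance(m: OmicsMatrix,
                    probe_to_gene: dict[str, str] | None = None) -> OmicsMatrix:
    """Methylation-view filter: average duplicate probes, keep variable features.

    ``probe_to_gene`` maps probe (feature) IDs to gene IDs; probes sharing a
    gene are averaged (arithmetic mean per sample). Features with zero
    variance are then dropped.
    """
    values, feature_ids = m.values, list(m.feature_ids)
    if probe_to_gene is not None:
        genes: list[str] = []
        cols: list[np.ndarray] = []
        seen: dict[str, int] = {}
        for j, probe in enumerate(feature_ids):
            gene = probe_to_gene.get(probe, probe)
            if gene in seen:
                cols[seen[gene]] = np.vstack([cols[seen[gene]], values[:, j]])
            else:
                seen[gene] = len(genes)
                genes.append(gene)
                cols.append(values[None, :, j])
        values = np.column_stack([c.mean(axis=0) for c in cols])
        feature_ids = genes
    variable = values.std(axis=0) > 0
    if not variable.any():
        raise ValueError(f"view '{m.view_name}': all features constant")
    return OmicsMatrix(m.view_name, list(m.sample_ids),
                       [f for f, k in zip(feature_ids, variable) if k],
                       values[:, variable])
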