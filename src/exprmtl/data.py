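"""Labeled expression datasets and one-vs-rest task construction.

The classifier consumes a normalized (VST-like, continuous) expression
matrix with one row per sample and one column per gene, plus a class
label per sample.  Every class becomes one binary task over the shared
predictor matrix: the task's response vector is +1 for samples of that
class and -1 otherwise, so a K-class dataset yields K coupled tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "TaskSet",
    "SplitResult",
    "build_tasks",
    "stratified_split",
    "read_expression_tsv",
    "read_labels_tsv",
    "load_dataset",
    "write_expression_tsv",
    "write_labels_tsv",
    "write_split_manifest",
]


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with per-sample class labels.

    Expression values must be finite (the pipeline sits downstream of
    normalization; missing values are a caller error).  Sample ids and
    gene ids must be unique.
    """

    X: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(c) for c in self.labels]
        n, p = self.X.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} matrix rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} matrix columns")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene ids are not unique")
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                "non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.labels:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def take(self, indices) -> "ExpressionDataset":
        """Row subset preserving the given order."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            X=self.X[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            gene_ids=list(self.gene_ids),
            labels=[self.labels[i] for i in indices],
        )

    def restrict_genes(self, genes) -> "ExpressionDataset":
        """Column subset; requested genes keep the dataset's own order."""
        wanted = set(genes)
        missing = wanted - set(self.gene_ids)
        if missing:
            raise KeyError(f"genes not in dataset: {sorted(missing)[:5]}")
        cols = [j for j, g in enumerate(self.gene_ids) if g in wanted]
        return ExpressionDataset(
            X=self.X[:, cols],
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[j] for j in cols],
            labels=list(self.labels),
        )

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, labels: pd.Series) -> "ExpressionDataset":
        """Build from a samples x genes DataFrame and a label Series.

        ``labels`` is joined on the DataFrame's index; every sample must
        have a label.
        """
        labels = labels.reindex(expr.index)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise KeyError(f"samples without a label: {missing[:5]}")
        return cls(
            X=expr.to_numpy(dtype=float),
            sample_ids=list(expr.index.astype(str)),
            gene_ids=list(expr.columns.astype(str)),
            labels=list(labels.astype(str)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class TaskSet:
    """Shared predictor matrix plus one +1/-1 response column per class."""

    X: np.ndarray
    Y: np.ndarray
    task_names: list[str]
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (self.X.shape[0], len(self.task_names)):
            raise ValueError(
                f"Y shape {self.Y.shape} does not match {self.X.shape[0]} samples "
                f"x {len(self.task_names)} tasks"
            )
        if not np.all(np.isin(self.Y, (-1.0, 1.0))):
            raise ValueError("Y entries must be +1/-1")
        if not np.all((self.Y == 1.0).sum(axis=1) == 1):
            raise ValueError("each sample must be positive for exactly one task")

    @property
    def n_tasks(self) -> int:
        return self.Y.shape[1]

    def labels(self) -> list[str]:
        """Recover the class label of every sample from Y."""
        idx = np.argmax(self.Y, axis=1)
        return [self.task_names[i] for i in idx]


@dataclass
class SplitResult:
    train: ExpressionDataset
    test: ExpressionDataset
    seed: int
    ratio: float


def build_tasks(data: ExpressionDataset, class_order: list[str] | None = None) -> TaskSet:
    """One-vs-rest task construction over a shared predictor matrix.

    Column ``i`` of ``Y`` is +1 where the sample's label equals
    ``task_names[i]`` and -1 elsewhere.  ``task_names`` defaults to the
    sorted distinct labels.
    """
    distinct = sorted(set(data.labels))
    if class_order is None:
        task_names = distinct
    else:
        task_names = [str(c) for c in class_order]
        if sorted(task_names) != distinct:
            raise ValueError(
                f"class_order {task_names} is not a permutation of the "
                f"observed classes {distinct}"
            )
    lab = np.asarray(data.labels, dtype=object)
    Y = np.where(lab[:, None] == np.asarray(task_names, dtype=object)[None, :], 1.0, -1.0)
    return TaskSet(
        X=data.X,
        Y=Y,
        task_names=task_names,
        gene_ids=list(data.gene_ids),
        sample_ids=list(data.sample_ids),
    )


def stratified_split(
    data: ExpressionDataset, test_fraction: float, seed: int
) -> SplitResult:
    """Seeded stratified train/test partition (the 8:2 protocol by default).

    Within each class, ``round(n_class * test_fraction)`` samples
    (round-half-up, at least 1, at most ``n_class - 1``) go to the test
    partition, chosen by the seeded generator; the remainder stay in
    train, so per-class proportions match the whole dataset within one
    sample.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    counts = data.class_counts()
    for cls in sorted(counts):
        if counts[cls] < 2:
            raise ValueError(
                f"class {cls!r} has only {counts[cls]} sample(s); "
                "stratified splitting needs at least 2 per class"
            )
    rng = np.random.default_rng(seed)
    labels = np.asarray(data.labels, dtype=object)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in sorted(counts):
        idx = np.flatnonzero(labels == cls)
        n_cls = idx.size
        n_test = int(np.floor(n_cls * test_fraction + 0.5))  # round half up
        n_test = min(max(n_test, 1), n_cls - 1)
        perm = rng.permutation(n_cls)
        test_idx.extend(idx[perm[:n_test]].tolist())
        train_idx.extend(idx[perm[n_test:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return SplitResult(
        train=data.take(train_idx),
        test=data.take(test_idx),
        seed=seed,
        ratio=test_fraction,
    )


# --- text I/O ---------------------------------------------------------------
#
# Expression TSV: header row of gene ids, first column sample ids,
# tab-separated floats.  Label TSV: two columns (sample id, class) with a
# header line.  Sample order is taken from the expression file; labels are
# joined by id and unmatched ids are an error.


def read_expression_tsv(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return expr


def read_labels_tsv(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] != 2:
        raise ValueError(f"label table must have 2 columns, found {tab.shape[1]}")
    return pd.Series(tab.iloc[:, 1].values, index=tab.iloc[:, 0].values)


def load_dataset(expression_path, labels_path) -> ExpressionDataset:
    expr = read_expression_tsv(expression_path)
    labels = read_labels_tsv(labels_path)
    return ExpressionDataset.from_dataframe(expr, labels)


def write_expression_tsv(data: ExpressionDataset, path) -> None:
    df = data.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_labels_tsv(data: ExpressionDataset, path) -> None:
    pd.DataFrame({"sample_id": data.sample_ids, "class": data.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_split_manifest(split: SplitResult, path) -> None:
    rows = [(s, "train") for s in split.train.sample_ids]
    rows += [(s, "test") for s in split.test.sample_ids]
    pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(
        path, sep="\t", index=False
    )
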