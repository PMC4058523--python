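"""Containers and TSV readers/writers for expression data, sample annotations
and miRNA→gene interaction edge lists.

All on-disk formats are tab-separated text with a single header line:

* expression matrix: ``feature_id<TAB>s1<TAB>s2...`` with one row per feature;
* sample annotation: ``sample_id<TAB>class_label<TAB>pair_key``;
* edge list: ``mirna_id<TAB>gene_id[<TAB>source]``.

Feature and sample identifiers are case-sensitive strings matched by exact
equality throughout the package; no alias resolution (miRBase versions, gene
symbol synonyms) is attempted.  miRNA and mRNA profiles of the same biological
specimen are linked through a shared ``pair_key``, never through column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("miRNA", "mRNA")
CLASS_LABELS = ("case", "control")


class DataValidationError(ValueError):
    """Raised when an input file or container violates a format invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A features × samples real-valued expression table.

    Parameters
    ----------
    data
        DataFrame indexed by feature id, columns are sample ids.
    feature_kind
        ``"miRNA"`` or ``"mRNA"``.
    log_scale
        Whether the values have already been log-transformed.  Guards against
        double transformation.
    """

    data: pd.DataFrame
    feature_kind: str
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise DataValidationError(
                f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        if self.data.shape[0] == 0:
            raise DataValidationError("no features")
        if self.data.shape[1] == 0:
            raise DataValidationError("no samples")
        _check_unique(self.data.index, "feature id")
        _check_unique(self.data.columns, "sample id")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise DataValidationError("expression values must be numeric")
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise DataValidationError(
                f"non-finite value at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression(path, feature_kind: str) -> ExpressionMatrix:
    """Read a features × samples expression TSV.

    Duplicate feature or sample ids and non-numeric cells are hard errors,
    reported with the offending identifier or row/column coordinates.
    Values are returned untouched (``log_scale=False``).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise DataValidationError(f"{path}: empty file")
    sample_ids = header.split("\t")[1:]
    _check_unique(sample_ids, "sample id")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[0] == 0:
        raise DataValidationError(f"{path}: no features")
    df.index = df.index.astype(str)
    df.index.name = None
    _check_unique(df.index, "feature id")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = df.index[np.argmax(bad.to_numpy())]
            raise DataValidationError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}"
            )
        if df[col].isna().any():
            row = df.index[np.argmax(df[col].isna().to_numpy())]
            raise DataValidationError(
                f"{path}: missing value at feature {row!r}, sample {col!r}"
            )
    return ExpressionMatrix(df.astype(float), feature_kind=feature_kind)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="feature_id")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace every value x by log2(x + pseudocount).

    Requires nonnegative input values and a positive pseudocount whenever any
    value equals zero; a matrix already on the log scale is rejected.
    """
    if m.log_scale:
        raise DataValidationError("matrix is already log-scale; refusing to transform twice")
    if pseudocount < 0:
        raise DataValidationError("pseudocount must be nonnegative")
    vals = m.values
    if np.any(vals < 0):
        r, c = np.argwhere(vals < 0)[0]
        raise DataValidationError(
            f"negative expression value at feature {m.feature_ids[r]!r}, "
            f"sample {m.sample_ids[c]!r}; cannot log-transform"
        )
    if pseudocount == 0 and np.any(vals == 0):
        raise DataValidationError("zero expression value with pseudocount 0")
    out = pd.DataFrame(
        np.log2(vals + pseudocount), index=m.data.index, columns=m.data.columns
    )
    return ExpressionMatrix(out, feature_kind=m.feature_kind, log_scale=True)


@dataclass
class SampleAnnotation:
    """Two-class design: one row per sample with class label and pair key.

    A ``pair_key`` links the miRNA profile and the mRNA profile measured on
    the same specimen.  When both profiles share one physical sample id, the
    pair key may simply equal the sample id.
    """

    table: pd.DataFrame  # columns: sample_id, class_label, pair_key

    def __post_init__(self) -> None:
        required = ["sample_id", "class_label", "pair_key"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"annotation missing columns: {missing}")
        self.table = self.table[required].astype(str).reset_index(drop=True)
        _check_unique(self.table["sample_id"], "sample id")
        bad = set(self.table["class_label"]) - set(CLASS_LABELS)
        if bad:
            raise DataValidationError(
                f"class labels must be in {CLASS_LABELS}, found {sorted(bad)}"
            )
        counts = self.table["class_label"].value_counts()
        for lbl in CLASS_LABELS:
            if counts.get(lbl, 0) < 2:
                raise DataValidationError(f"need at least 2 samples of class {lbl!r}")

    def labels_for(self, sample_ids) -> np.ndarray:
        """Class labels aligned to ``sample_ids``; every id must be annotated."""
        lut = dict(zip(self.table["sample_id"], self.table["class_label"]))
        out = []
        for s in sample_ids:
            if s not in lut:
                raise DataValidationError(f"sample {s!r} has no annotation")
            out.append(lut[s])
        return np.asarray(out)

    def samples_of(self, class_label: str) -> list[str]:
        t = self.table
        return list(t.loc[t["class_label"] == class_label, "sample_id"])


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def paired_samples(
    ann: SampleAnnotation, mirna_samples, gene_samples
) -> pd.DataFrame:
    """Resolve miRNA/mRNA sample pairs through shared pair keys.

    Returns a DataFrame ``pair_key, mirna_sample, gene_sample, class_label``
    sorted by pair key, covering every pair key represented in *both*
    matrices.  A pair key with more than one sample in either matrix, or with
    conflicting class labels between its two profiles, is a hard error; keys
    present in only one matrix are dropped with a log message.
    """
    mset, gset = set(mirna_samples), set(gene_samples)
    rows = []
    dropped = 0
    for key, grp in ann.table.groupby("pair_key", sort=True):
        in_m = [s for s in grp["sample_id"] if s in mset]
        in_g = [s for s in grp["sample_id"] if s in gset]
        if len(in_m) > 1 or len(in_g) > 1:
            raise DataValidationError(
                f"pair_key {key!r} is ambiguous: {len(in_m)} miRNA and "
                f"{len(in_g)} mRNA samples"
            )
        if not in_m or not in_g:
            dropped += 1
            continue
        labels = set(grp.loc[grp["sample_id"].isin([in_m[0], in_g[0]]), "class_label"])
        if len(labels) != 1:
            raise DataValidationError(
                f"pair_key {key!r} has conflicting class labels {sorted(labels)}"
            )
        rows.append((key, in_m[0], in_g[0], labels.pop()))
    if dropped:
        logger.info("paired_samples: dropped %d pair keys absent from one matrix", dropped)
    return pd.DataFrame(
        rows, columns=["pair_key", "mirna_sample", "gene_sample", "class_label"]
    )


@dataclass
class InteractionEdgeList:
    """Reference miRNA→gene interactions as a deduplicated directed edge set.

    The two endpoint namespaces must be disjoint (bipartite by construction);
    an id occurring both as a miRNA and as a gene indicates an id-scheme
    mixup and is rejected.
    """

    edges: set = field(default_factory=set)  # {(mirna_id, gene_id)}
    provenance: dict = field(default_factory=dict)  # (mirna, gene) -> source tag

    def __post_init__(self) -> None:
        self.edges = {(str(m), str(g)) for m, g in self.edges}
        overlap = self.mirnas & self.genes
        if overlap:
            raise DataValidationError(
                f"miRNA and gene namespaces overlap: {sorted(overlap)[:5]}"
            )

    @property
    def mirnas(self) -> set:
        return {m for m, _ in self.edges}

    @property
    def genes(self) -> set:
        return {g for _, g in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge) -> bool:
        return tuple(edge) in self.edges


def read_edge_list(path) -> InteractionEdgeList:
    """Read a miRNA→gene edge-list TSV (header line required).

    Rows may carry an optional third column with a provenance/source tag.
    Duplicated (miRNA, gene) rows are collapsed (first provenance kept).
    """
    edges: set = set()
    provenance: dict = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DataValidationError(f"{path}: no edges")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (2, 3) or not parts[0] or not parts[1]:
                raise DataValidationError(f"{path}: malformed row at line {lineno}")
            edge = (parts[0], parts[1])
            if edge not in edges:
                edges.add(edge)
                if len(parts) == 3:
                    provenance[edge] = parts[2]
    if not edges:
        raise DataValidationError(f"{path}: no edges")
    out = InteractionEdgeList(edges, provenance)
    logger.info(
        "read_edge_list: %d edges, %d miRNAs, %d genes from %s",
        len(out), len(out.mirnas), len(out.genes), path,
    )
    return out


def write_edge_list(el: InteractionEdgeList, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tsource\n")
        for m, g in sorted(el.edges):
            fh.write(f"{m}\t{g}\t{el.provenance.get((m, g), '')}\n")
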