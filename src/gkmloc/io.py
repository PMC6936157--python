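"""Dataset and matrix I/O.

Sequences come in as multi-FASTA, either one file per class (label =
file stem) or any number of files plus a sidecar TSV label map
(``id<TAB>label``).  Feature matrices go out as TSV (header = canonical
pattern strings) or sparse LIBSVM lines; both round-trip integer counts
losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "LabeledDataset",
    "read_fasta",
    "read_label_map",
    "write_fasta",
    "write_matrix",
    "read_matrix",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Records of (id, sequence, class label) with unique ids."""

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for rid, seq, label in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"empty sequence for id {rid!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted({label for _, _, label in self.records}))

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq, _ in self.records]

    @property
    def labels(self) -> list[str]:
        return [label for _, _, label in self.records]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, label in self.records:
            out[label] = out.get(label, 0) + 1
        return out


def read_label_map(path) -> dict[str, str]:
    """Read a TSV ``id<TAB>label`` map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
            rid, label = parts[0].strip(), parts[1].strip()
            if rid in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {rid!r}")
            out[rid] = label
    return out


def read_fasta(paths, label_map=None) -> LabeledDataset:
    """Read one or more FASTA files into a labeled dataset.

    With ``label_map`` (a path or a dict), every record id must appear
    in the map.  Without it, each file's stem is the class label for all
    its records.  Sequences are uppercased and whitespace-stripped;
    duplicate ids and empty files are rejected by name.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if isinstance(label_map, (str, Path)):
        label_map = read_label_map(label_map)
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for path in paths:
        path = Path(path)
        n_before = len(records)
        for rec in SeqIO.parse(str(path), "fasta"):
            rid = rec.id
            if not rid:
                raise ValueError(f"{path}: malformed FASTA header (empty id)")
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r} (in {path})")
            seen.add(rid)
            seq = str(rec.seq).upper().replace(" ", "").replace("\t", "")
            if label_map is not None:
                if rid not in label_map:
                    raise ValueError(f"id {rid!r} missing from label map")
                label = label_map[rid]
            else:
                label = path.stem
            records.append((rid, seq, label))
        if len(records) == n_before:
            raise ValueError(f"{path}: no FASTA records")
    ds = LabeledDataset(records=records)
    logger.info("read %d sequences in %d classes: %s",
                len(ds), len(ds.classes), ds.class_counts())
    return ds


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA, 60 columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_matrix(X, ids, columns, path, fmt: str = "tsv", labels=None) -> None:
    """Write a feature matrix as TSV or sparse LIBSVM.

    TSV rows carry the sequence id; LIBSVM lines are
    ``label index:value`` with 1-based indices into ``columns`` (labels
    default to 0).
    """
    X = np.asarray(X)
    if X.shape[0] != len(ids):
        raise ValueError(f"{X.shape[0]} rows but {len(ids)} ids")
    if X.ndim != 2 or X.shape[1] != len(columns):
        raise ValueError(f"matrix width {X.shape[1:]} != {len(columns)} columns")
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(columns) + "\n")
            for rid, row in zip(ids, X):
                fh.write(rid + "\t" + "\t".join(_fmt_num(v) for v in row) + "\n")
    elif fmt == "libsvm":
        if labels is None:
            labels = [0] * len(ids)
        with open(path, "w") as fh:
            for label, row in zip(labels, X):
                nz = " ".join(f"{j + 1}:{_fmt_num(v)}" for j, v in enumerate(row) if v != 0)
                fh.write(f"{label} {nz}".rstrip() + "\n")
    else:
        raise ValueError(f"format must be tsv|libsvm, got {fmt!r}")


def _fmt_num(v) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def read_matrix(path):
    """Read a TSV feature matrix back: ``(X, ids, columns)``."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: expected an 'id' header column")
        columns = header[1:]
        ids, rows = [], []
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}: row width mismatch for {parts[0]!r}")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    X = np.array(rows) if rows else np.empty((0, len(columns)))
    return X, ids, columns


def write_report(report, path) -> None:
    """Write an EvalReport as TSV: one row per class plus an OA footer."""
    with open(path, "w") as fh:
        fh.write("class\tSn\tSp\tMCC\n")
        for cls, sn, sp, mcc in report.to_rows():
            fh.write(f"{cls}\t{sn:.4f}\t{sp:.4f}\t{mcc:.4f}\n")
        fh.write(f"OA\t{report.oa:.4f}\t\t\n")
        if report.C is not None:
            fh.write(f"# C={report.C:g} gamma={report.gamma:g}\n")
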