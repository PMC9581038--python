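"""Reading, validating and writing labelled epitope datasets.

An epitope record is a short peptide (5-50 residues over the 20 standard
amino acids) annotated with a 4-bit antibody-class label vector in the fixed
order (IgG, IgE, IgA, IgM).  Two on-disk dialects are supported:

* FASTA with the label bits in the description line after a pipe, e.g.
  ``>ep1|1 0 0 1`` for an IgG+IgM binder;
* a delimited table (TSV or CSV, chosen by file extension) with columns
  ``id``, ``sequence``, ``IgG``, ``IgE``, ``IgA``, ``IgM``.

Records failing validation (non-standard residues, length outside 5-50) are
dropped with a logged warning rather than imputed: the downstream encoders
are defined only over the 20-letter alphabet.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical antibody-class label order used everywhere in the package.
LABEL_NAMES: tuple[str, str, str, str] = ("IgG", "IgE", "IgA", "IgM")

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

MIN_LENGTH = 5
MAX_LENGTH = 50

LabelVector = tuple[int, int, int, int]


class DatasetError(Exception):
    """Fatal problem with an input dataset."""


@dataclass(frozen=True)
class EpitopeRecord:
    """One peptide with an optional 4-bit antibody-class label vector."""

    id: str
    sequence: str
    labels: LabelVector | None = None

    def validate(self, require_labels: bool = False) -> list[str]:
        """Return a list of human-readable validation failures (empty if valid)."""
        problems: list[str] = []
        n = len(self.sequence)
        if not (MIN_LENGTH <= n <= MAX_LENGTH):
            problems.append(f"length {n} outside [{MIN_LENGTH}, {MAX_LENGTH}]")
        bad = sorted(set(self.sequence) - set(AMINO_ACIDS))
        if bad:
            problems.append(f"non-standard residue(s) {''.join(bad)}")
        if self.labels is not None:
            if len(self.labels) != 4 or any(b not in (0, 1) for b in self.labels):
                problems.append(f"malformed label vector {self.labels!r}")
        elif require_labels:
            problems.append("missing label vector")
        if require_labels and self.labels is not None and sum(self.labels) == 0:
            problems.append("all-zero label vector on a training record")
        return problems


@dataclass
class Dataset:
    """An ordered collection of epitope records with the fixed label order."""

    records: list[EpitopeRecord] = field(default_factory=list)
    label_names: tuple[str, ...] = LABEL_NAMES

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_matrix(self):
        """Labels as an (n, 4) int array; raises if any record is unlabelled."""
        import numpy as np

        rows = []
        for r in self.records:
            if r.labels is None:
                raise DatasetError(f"record {r.id!r} has no labels")
            rows.append(r.labels)
        return np.asarray(rows, dtype=int).reshape(len(rows), 4)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(records=[self.records[i] for i in indices],
                       label_names=self.label_names)


def _parse_label_bits(text: str) -> LabelVector:
    bits = text.replace(",", " ").split()
    if len(bits) != 4 or any(b not in ("0", "1") for b in bits):
        raise ValueError(f"malformed label {text!r}")
    return tuple(int(b) for b in bits)  # type: ignore[return-value]


def _make_record(rec_id: str, seq: str, labels: LabelVector | None) -> EpitopeRecord:
    return EpitopeRecord(id=str(rec_id), sequence=str(seq).strip().upper(), labels=labels)


def _filter_records(raw: Iterable[EpitopeRecord], training: bool) -> Dataset:
    kept: list[EpitopeRecord] = []
    seen_ids: set[str] = set()
    n_dropped = 0
    for rec in raw:
        problems = rec.validate(require_labels=training)
        if rec.id in seen_ids:
            problems.append("duplicate record id")
        if problems:
            n_dropped += 1
            logger.warning("dropping record %s: %s", rec.id, "; ".join(problems))
            continue
        seen_ids.add(rec.id)
        kept.append(rec)
    if n_dropped:
        logger.warning("dropped %d invalid record(s), kept %d", n_dropped, len(kept))
    # Duplicate sequences with different labels are kept as-is but reported,
    # mirroring how curated epitope collections retain assay-level duplicates.
    dup = [s for s, c in Counter(r.sequence for r in kept).items() if c > 1]
    if dup:
        logger.info("%d sequence(s) occur more than once (kept as-is)", len(dup))
    return Dataset(records=kept)


def read_dataset(path: str | Path, format: str | None = None,
                 training: bool = True) -> Dataset:
    """Read a labelled epitope dataset from FASTA or a delimited table.

    Parameters
    ----------
    path:
        Input file.  ``format`` is inferred from the extension when omitted:
        ``.fasta``/``.fa``/``.faa`` -> fasta, ``.tsv``/``.csv``/``.txt`` -> table.
    format:
        ``"fasta"`` or ``"table"``.
    training:
        In training mode a malformed or missing label is fatal; in prediction
        mode such records are kept unlabelled.

    Returns
    -------
    Dataset
        Only records passing validation; rejects are logged with reasons.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = "fasta" if suffix in (".fasta", ".fa", ".faa") else "table"
    if format == "fasta":
        raw = list(_iter_fasta(path, training))
    elif format == "table":
        raw = list(_iter_table(path, training))
    else:
        raise DatasetError(f"unknown format {format!r}")
    return _filter_records(raw, training)


def _iter_fasta(path: Path, training: bool) -> Iterable[EpitopeRecord]:
    for seqrec in SeqIO.parse(str(path), "fasta"):
        header = seqrec.description
        try:
            seq_text = str(seqrec.seq)
        except UnicodeDecodeError:
            logger.warning("dropping record %r: undecodable bytes in sequence",
                           header)
            continue
        labels: LabelVector | None = None
        if "|" in header:
            rec_id, _, label_text = header.partition("|")
            try:
                labels = _parse_label_bits(label_text)
            except ValueError:
                if training:
                    raise DatasetError(
                        f"malformed label in header {header!r} (training mode)")
                logger.warning("record %s: unparsable label, treated as unlabelled",
                               rec_id.strip())
        else:
            rec_id = header
            if training:
                raise DatasetError(
                    f"header {header!r} carries no label (training mode)")
        yield _make_record(rec_id.strip(), seq_text, labels)


def _iter_table(path: Path, training: bool) -> Iterable[EpitopeRecord]:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"id", "sequence"}
    if not required.issubset(df.columns):
        raise DatasetError(f"table must have columns id, sequence; got {list(df.columns)}")
    has_labels = all(name in df.columns for name in LABEL_NAMES)
    if training and not has_labels:
        raise DatasetError(f"training table must carry label columns {LABEL_NAMES}")
    for _, row in df.iterrows():
        labels: LabelVector | None = None
        if has_labels:
            try:
                labels = _parse_label_bits(" ".join(str(row[n]) for n in LABEL_NAMES))
            except ValueError:
                if training:
                    raise DatasetError(f"malformed label for record {row['id']!r}")
                logger.warning("record %s: unparsable label, treated as unlabelled",
                               row["id"])
        yield _make_record(row["id"], row["sequence"], labels)


def write_dataset(ds: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset in FASTA (labels in header) or table form."""
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fasta", ".fa", ".faa") else "table"
    if format == "fasta":
        # plain writer: Bio.SeqIO would insert a space before the description,
        # breaking the ">id|b b b b" label dialect on re-read
        with open(path, "w") as fh:
            for r in ds.records:
                header = (f"{r.id}|{' '.join(map(str, r.labels))}"
                          if r.labels is not None else r.id)
                fh.write(f">{header}\n{r.sequence}\n")
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        rows = []
        for r in ds.records:
            row = {"id": r.id, "sequence": r.sequence}
            if r.labels is not None:
                row.update(dict(zip(LABEL_NAMES, r.labels)))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def combination_census(ds: Dataset) -> dict[LabelVector, int]:
    """Count records per exact 4-bit label combination."""
    census: Counter = Counter()
    for r in ds.records:
        if r.labels is None:
            raise DatasetError(f"record {r.id!r} is unlabelled; census needs labels")
        census[r.labels] += 1
    return dict(census)


def write_predictions(records: Sequence[EpitopeRecord], predicted_labels,
                      scores, path: str | Path) -> None:
    """Write per-record class calls and scores as a TSV.

    One row per record with id, sequence, the four 0/1 calls and the four
    per-class scores in [0, 1].  An empty input yields a header-only file.
    """
    import numpy as np

    predicted_labels = np.asarray(predicted_labels, dtype=int).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).reshape(-1, 4)
    if len(records) != predicted_labels.shape[0] or len(records) != scores.shape[0]:
        raise DatasetError(
            f"length mismatch: {len(records)} records vs "
            f"{predicted_labels.shape[0]} label rows / {scores.shape[0]} score rows")
    rows = []
    for rec, bits, sc in zip(records, predicted_labels, scores):
        row = {"id": rec.id, "sequence": rec.sequence}
        row.update({name: int(b) for name, b in zip(LABEL_NAMES, bits)})
        row.update({f"score_{name}": float(s) for name, s in zip(LABEL_NAMES, sc)})
        rows.append(row)
    columns = (["id", "sequence"] + list(LABEL_NAMES)
               + [f"score_{n}" for n in LABEL_NAMES])
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> tuple[Dataset, "pd.DataFrame"]:
    """Read a prediction TSV back; returns the records and the full frame."""
    df = pd.read_csv(path, sep="\t")
    records = [
        EpitopeRecord(id=str(row["id"]), sequence=str(row["sequence"]),
                      labels=tuple(int(row[n]) for n in LABEL_NAMES))
        for _, row in df.iterrows()
    ]
    return Dataset(records=records), df
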