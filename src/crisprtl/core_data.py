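"""Domain types, dataset I/O, normalization, and input encodings.

A guide is handled as a 21-nt DNA string: the 20-nt protospacer plus the
first PAM base. The last two PAM bases are fixed GG in all supported
datasets, so they are stripped on ingestion and reconstructed wherever a
23-nt comparison is required. The optional 30-nt context is laid out as
4 upstream + 20 guide + 3 PAM + 3 downstream, with 0-based half-open
coordinates throughout: context30[4:25] == guide21 and
context30[25:27] == "GG".

Two encodings feed the two model families:

* recurrent: a start symbol followed by the 21 nucleotides, one-hot over a
  5-letter alphabet (start, A, C, G, T), concatenated with 11 sequence
  bio-features and, for the multi-task model, a 3-way enzyme indicator;
* convolutional: the 30-nt context as a 30x4 one-hot matrix plus a scalar
  binding-energy feature carried as a side input.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}
#: Token alphabet for the recurrent encoder: start symbol then the 4 bases.
RNN_ALPHABET = "^" + ALPHABET
ENZYMES = ("WT", "Esp", "HF")

GUIDE_LEN = 21
CONTEXT_LEN = 30
#: 30-mer layout, 0-based half-open.
CONTEXT_GUIDE = (4, 25)
CONTEXT_PAM_GG = (25, 27)

#: Published sizes of the high-throughput source datasets (guides per
#: condition), kept as reproduction metadata for the optional real-data
#: pipeline. The combined count is the sum over the three enzyme screens.
PUBLISHED_DATASET_SIZES = {
    "DeepHF WT": 55604,
    "DeepHF Esp": 58167,
    "DeepHF HF": 56888,
    "CRISPRon": 23902,
}
PUBLISHED_COMBINED_DEEPHF = 170659
PUBLISHED_COMBINED_DEEPHF_FILTERED = 169269


class DataError(ValueError):
    """Raised for malformed datasets or invalid operations on them."""


def clean_sequence(seq: str) -> str:
    """Uppercase and map U->T; raises on any residue outside {A,C,G,T}."""
    s = seq.strip().upper().replace("U", "T")
    if not s or any(c not in LETTER_INDEX for c in s):
        raise DataError(f"invalid nucleotide sequence: {seq!r}")
    return s


@dataclass
class GuideRecord:
    """One gRNA with its sequence context and per-condition efficiencies."""

    id: str
    guide21: str
    context30: str | None = None
    efficiencies: dict[str, float] = field(default_factory=dict)
    biofeatures: np.ndarray | None = None
    energy_score: float | None = None

    def __post_init__(self):
        if len(self.guide21) != GUIDE_LEN or any(c not in LETTER_INDEX for c in self.guide21):
            raise DataError(f"record {self.id}: guide21 must be 21 nt over ACGT")
        if self.context30 is not None:
            c = self.context30
            if len(c) != CONTEXT_LEN:
                raise DataError(f"record {self.id}: context30 must be 30 nt")
            if c[CONTEXT_GUIDE[0]:CONTEXT_GUIDE[1]] != self.guide21:
                raise DataError(f"record {self.id}: context30 does not embed guide21 at 4..24")
            if c[CONTEXT_PAM_GG[0]:CONTEXT_PAM_GG[1]] != "GG":
                raise DataError(f"record {self.id}: PAM positions 25-26 must be GG")
        for label, v in self.efficiencies.items():
            if not (0.0 <= v <= 1.0):
                raise DataError(f"record {self.id}: efficiency {label}={v} outside [0,1]")

    @property
    def guide23(self) -> str:
        """The 23-nt guide+PAM with the implicit GG restored."""
        return self.guide21 + "GG"


@dataclass
class Dataset:
    """Ordered collection of guide records sharing condition labels."""

    records: list[GuideRecord]
    name: str = ""
    condition_labels: list[str] = field(default_factory=list)
    provenance: str = ""
    #: per-condition (min, max) of the raw efficiencies before normalization,
    #: recorded so predictions can be mapped back to the original scale.
    norm_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DataError(f"dataset {self.name!r}: duplicate record ids")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, GuideRecord]:
        return {r.id: r for r in self.records}

    def subset(self, ids, name: str | None = None) -> "Dataset":
        keep = set(ids)
        return Dataset(
            records=[r for r in self.records if r.id in keep],
            name=name if name is not None else self.name,
            condition_labels=list(self.condition_labels),
            provenance=self.provenance,
            norm_params=dict(self.norm_params),
        )


@dataclass
class EncodedBatch:
    """Model-ready arrays for one batch of guides.

    ``seq`` is one-hot: (n, 22, 5) for the recurrent encoder (start symbol +
    21 nt) or (n, 30, 4) for the convolutional one. ``extra`` holds the
    non-sequence side inputs (bio-features [+ enzyme indicator], or the
    energy score). ``y`` may contain NaN where no efficiency is observed.
    """

    kind: str  # "rnn" | "cnn"
    seq: np.ndarray
    extra: np.ndarray
    y: np.ndarray
    ids: list[str]

    @property
    def n(self) -> int:
        return self.seq.shape[0]

    def take(self, idx) -> "EncodedBatch":
        return EncodedBatch(self.kind, self.seq[idx], self.extra[idx],
                            self.y[idx], [self.ids[i] for i in np.atleast_1d(idx)])


# ---------------------------------------------------------------------------
# dataset I/O


def _parse_sequence(raw: str) -> tuple[str, str | None]:
    """Return (guide21, context30-or-None) from a 21/23/30-nt input."""
    seq = clean_sequence(raw)
    if len(seq) == GUIDE_LEN:
        return seq, None
    if len(seq) == 23:
        if not seq.endswith("GG"):
            raise DataError(f"23-nt sequence must end in GG, got ...{seq[-2:]}")
        return seq[:GUIDE_LEN], None
    if len(seq) == CONTEXT_LEN:
        if seq[CONTEXT_PAM_GG[0]:CONTEXT_PAM_GG[1]] != "GG":
            raise DataError("30-nt context must have GG at positions 25-26")
        return seq[CONTEXT_GUIDE[0]:CONTEXT_GUIDE[1]], seq
    raise DataError(f"sequence length {len(seq)} not in (21, 23, 30)")


def read_dataset(path, schema: dict | None = None, name: str | None = None) -> Dataset:
    """Read a CSV/TSV guide-efficiency table.

    ``schema`` maps roles to column names: ``{"sequence": col, "id": col,
    "efficiency": {label: col, ...}, "energy": col}``. Only ``sequence`` and
    ``efficiency`` are required; when ``id`` is absent, row numbers are used.
    Rows with an invalid sequence are rejected (collected with their line
    numbers); an efficiency cell that does not parse becomes an absent entry
    for that condition. Zero surviving rows is a hard error.
    """
    path = Path(path)
    schema = dict(schema or {})
    delim = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        seq_col = schema.get("sequence") or next(
            (c for c in header if c.lower() in {"sequence", "seq", "guide", "grna", "21mer", "23mer", "30mer"}),
            None,
        )
        if seq_col is None:
            raise DataError(f"{path}: no sequence column found; pass schema={{'sequence': ...}}")
        id_col = schema.get("id") or next(
            (c for c in header if c.lower() in {"id", "name", "guide_id"}), None)
        energy_col = schema.get("energy") or next(
            (c for c in header if c.lower() in {"energy", "energy_score",
                                                "crisproff_score", "dgb"}), None)
        eff_map = schema.get("efficiency")
        if eff_map is None:
            eff_map = {c: c for c in header if c not in {seq_col, id_col, energy_col}}

        records, rejected = [], []
        for lineno, row in enumerate(reader, start=2):
            try:
                guide21, context30 = _parse_sequence(row[seq_col])
            except DataError as exc:
                rejected.append((lineno, str(exc)))
                continue
            effs = {}
            for label, col in eff_map.items():
                try:
                    v = float(row[col])
                except (TypeError, ValueError, KeyError):
                    continue
                if np.isfinite(v):
                    effs[label] = v
            if not effs:
                rejected.append((lineno, "no parseable efficiency"))
                continue
            energy = None
            if energy_col:
                try:
                    energy = float(row[energy_col])
                except (TypeError, ValueError, KeyError):
                    energy = None
            rid = row[id_col] if id_col else f"row{lineno}"
            # raw efficiencies may be on any scale; clamp to the record
            # invariant only after normalization, so store raw in a side map
            rec = GuideRecord(id=rid, guide21=guide21, context30=context30,
                              efficiencies={}, energy_score=energy)
            rec._raw_efficiencies = effs  # type: ignore[attr-defined]
            records.append(rec)

    if not records:
        raise DataError(f"{path}: zero valid rows ({len(rejected)} rejected)")

    labels = list(eff_map)
    ds = Dataset(records=records, name=name or path.stem, condition_labels=labels,
                 provenance=str(path))
    ds.rejected_rows = rejected  # type: ignore[attr-defined]
    # If raw values are already within [0,1] they are stored directly and
    # normalize_dataset is still available (and idempotent in effect);
    # otherwise they stay raw until normalize_dataset is called.
    for rec in records:
        raw = rec._raw_efficiencies  # type: ignore[attr-defined]
        if all(0.0 <= v <= 1.0 for v in raw.values()):
            rec.efficiencies = dict(raw)
    return ds


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset back to CSV (sequence, per-condition efficiencies)."""
    path = Path(path)
    labels = dataset.condition_labels
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        has_energy = any(r.energy_score is not None for r in dataset)
        head = ["id", "sequence"] + labels + (["energy"] if has_energy else [])
        writer.writerow(head)
        for rec in dataset:
            seq = rec.context30 if rec.context30 is not None else rec.guide21
            row = [rec.id, seq]
            row += [repr(rec.efficiencies[l]) if l in rec.efficiencies else ""
                    for l in labels]
            if has_energy:
                row.append("" if rec.energy_score is None else repr(rec.energy_score))
            writer.writerow(row)


def write_norm_sidecar(dataset: Dataset, path) -> None:
    with open(path, "w") as fh:
        json.dump({"dataset": dataset.name,
                   "minmax": {k: list(v) for k, v in dataset.norm_params.items()}},
                  fh, indent=2)


def read_fasta_guides(path) -> list[GuideRecord]:
    """Read guides from FASTA (21/23/30-nt entries) for scanning/prediction."""
    from Bio import SeqIO

    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        guide21, context30 = _parse_sequence(str(entry.seq))
        records.append(GuideRecord(id=entry.id, guide21=guide21, context30=context30))
    return records


# ---------------------------------------------------------------------------
# normalization


def minmax_normalize(values) -> np.ndarray:
    """Map values affinely onto [0,1]; rank order is preserved.

    Raises on fewer than 2 distinct finite values (a constant column cannot
    be normalized).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise DataError("minmax_normalize expects a 1-D vector")
    finite = v[np.isfinite(v)]
    if finite.size < 2 or np.isclose(finite.min(), finite.max()):
        raise DataError("constant or near-empty column cannot be min-max normalized")
    lo, hi = finite.min(), finite.max()
    return (v - lo) / (hi - lo)


def normalize_dataset(dataset: Dataset) -> Dataset:
    """Min-max normalize each condition column in place; records raw min/max.

    Applied per dataset before any filtering or splitting, so later removals
    do not change the scale.
    """
    for label in dataset.condition_labels:
        raw = np.array([
            rec._raw_efficiencies.get(label, np.nan)  # type: ignore[attr-defined]
            if hasattr(rec, "_raw_efficiencies") else rec.efficiencies.get(label, np.nan)
            for rec in dataset
        ])
        try:
            scaled = minmax_normalize(raw)
        except DataError as exc:
            raise DataError(f"condition {label!r}: {exc}") from exc
        finite = raw[np.isfinite(raw)]
        dataset.norm_params[label] = (float(finite.min()), float(finite.max()))
        for rec, s in zip(dataset.records, scaled):
            if np.isfinite(s):
                rec.efficiencies[label] = float(s)
            else:
                rec.efficiencies.pop(label, None)
    return dataset


# ---------------------------------------------------------------------------
# encodings


def _onehot_rnn(guide21: str) -> np.ndarray:
    out = np.zeros((GUIDE_LEN + 1, len(RNN_ALPHABET)))
    out[0, 0] = 1.0  # start symbol
    for i, c in enumerate(guide21):
        out[i + 1, 1 + LETTER_INDEX[c]] = 1.0
    return out


def _onehot_cnn(context30: str) -> np.ndarray:
    out = np.zeros((CONTEXT_LEN, len(ALPHABET)))
    for i, c in enumerate(context30):
        out[i, LETTER_INDEX[c]] = 1.0
    return out


def encode_rnn(records, condition: str | None = None,
               enzymes: tuple[str, ...] = ENZYMES) -> EncodedBatch:
    """Encode guides for the recurrent model.

    ``condition`` names the enzyme screen a batch came from and must be given
    exactly when the model is multi-task; it appends a one-hot indicator of
    size ``len(enzymes)`` to the bio-feature block. Targets are taken from
    ``record.efficiencies[condition]`` (multi-task) or from the single stored
    efficiency (single-task); absent values become NaN.
    """
    records = list(records)
    seq = np.stack([_onehot_rnn(r.guide21) for r in records]) if records else \
        np.zeros((0, GUIDE_LEN + 1, len(RNN_ALPHABET)))
    extras, ys, ids = [], [], []
    for r in records:
        if r.biofeatures is None:
            raise DataError(
                f"record {r.id} has no bio-features; run biofeatures.attach_biofeatures first")
        bf = np.asarray(r.biofeatures, dtype=float)
        if condition is not None:
            if condition not in enzymes:
                raise DataError(f"unknown condition {condition!r}; expected one of {enzymes}")
            ind = np.zeros(len(enzymes))
            ind[enzymes.index(condition)] = 1.0
            bf = np.concatenate([bf, ind])
            y = r.efficiencies.get(condition, np.nan)
        else:
            y = next(iter(r.efficiencies.values()), np.nan)
        extras.append(bf)
        ys.append(y)
        ids.append(r.id)
    extra = np.stack(extras) if extras else np.zeros((0, 11))
    return EncodedBatch("rnn", seq, extra, np.asarray(ys, dtype=float), ids)


def decode_rnn(seq_onehot: np.ndarray) -> list[str]:
    """Inverse of the recurrent sequence encoding (drops the start symbol)."""
    guides = []
    for mat in seq_onehot:
        tokens = mat.argmax(axis=1)
        if mat[0, 0] != 1.0 or (tokens[1:] == 0).any():
            raise DataError("not a valid start+21nt one-hot encoding")
        guides.append("".join(ALPHABET[t - 1] for t in tokens[1:]))
    return guides


def encode_cnn(records) -> EncodedBatch:
    """Encode 30-nt contexts for the convolutional model (energy side input)."""
    records = list(records)
    seqs, extras, ys, ids = [], [], [], []
    for r in records:
        if r.context30 is None:
            raise DataError(f"record {r.id} has no 30-nt context")
        if r.energy_score is None:
            raise DataError(f"record {r.id} has no energy score; "
                            "run biofeatures.attach_energy_scores first")
        seqs.append(_onehot_cnn(r.context30))
        extras.append([float(r.energy_score)])
        ys.append(next(iter(r.efficiencies.values()), np.nan))
        ids.append(r.id)
    seq = np.stack(seqs) if seqs else np.zeros((0, CONTEXT_LEN, len(ALPHABET)))
    extra = np.asarray(extras, dtype=float) if extras else np.zeros((0, 1))
    return EncodedBatch("cnn", seq, extra, np.asarray(ys, dtype=float), ids)
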