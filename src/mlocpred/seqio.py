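"""Reading, sanitizing and writing mRNA sequence data and label mappings.

Sequences are handled on the DNA alphabet {A, C, G, T}; RNA input is
accepted and U is mapped to T.  Each record carries exactly one of the
five subcellular locales.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The five subcellular locales, in canonical (alphabetical) order.  This
#: order fixes class order everywhere downstream (probability columns,
#: confusion-matrix axes, argmax tie-breaks).
LOCALES: tuple[str, ...] = ("Cytoplasm", "ER", "ExR", "Mitochondria", "Nucleus")

VALID_BASES = frozenset("ACGT")

#: Largest k used by any encoder; shorter sequences cannot be featurized.
MIN_SEQUENCE_LENGTH = 5

AmbiguousPolicy = Literal["reject", "strip"]


class SequenceRejected(ValueError):
    """A raw sequence could not be sanitized under the active policy."""


@dataclass(frozen=True)
class NucleotideSequence:
    """One sanitized mRNA sequence.

    ``id`` is the FASTA header token up to the first whitespace;
    ``description`` keeps the full header.  ``bases`` contains only
    A/C/G/T.
    """

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r}: empty bases")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class LabeledRecord:
    """A sanitized sequence with its single subcellular locale."""

    sequence: NucleotideSequence
    label: str

    def __post_init__(self) -> None:
        if self.label not in LOCALES:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {LOCALES}"
            )


def sanitize_sequence(
    raw: str,
    policy: AmbiguousPolicy = "reject",
    min_length: int = MIN_SEQUENCE_LENGTH,
) -> str:
    """Uppercase, map U->T, and resolve non-ACGT characters.

    Parameters
    ----------
    raw:
        Raw sequence string (DNA or RNA alphabet, any case).
    policy:
        ``"reject"`` (default) raises :class:`SequenceRejected` on any
        ambiguous base; ``"strip"`` silently removes them.
    min_length:
        Sequences shorter than this after sanitization are rejected;
        the encoders need at least 5 nt.

    Raises
    ------
    SequenceRejected
        If the sequence is empty, contains ambiguous bases under the
        reject policy, or is too short after sanitization.
    """
    if not raw:
        raise SequenceRejected("empty sequence")
    s = raw.upper().replace("U", "T")
    extra = set(s) - VALID_BASES
    if extra:
        if policy == "reject":
            raise SequenceRejected(
                f"ambiguous base: contains {sorted(extra)}"
            )
        s = "".join(c for c in s if c in VALID_BASES)
    if not s:
        raise SequenceRejected("empty after removing ambiguous bases")
    if len(s) < min_length:
        raise SequenceRejected(
            f"length {len(s)} < minimum {min_length} required by encoders"
        )
    return s


def read_fasta(
    path: str | Path,
    policy: AmbiguousPolicy = "reject",
    on_reject: Literal["drop", "error"] = "drop",
) -> list[NucleotideSequence]:
    """Read a FASTA file into sanitized :class:`NucleotideSequence` records.

    Records whose sequence fails sanitization are dropped with a logged
    warning (``on_reject="drop"``, default) or raise (``"error"``).
    Duplicate ids raise a ``ValueError`` naming the duplicate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            bases = sanitize_sequence(str(rec.seq), policy=policy)
        except SequenceRejected as exc:
            if on_reject == "error":
                raise ValueError(f"record {rec.id!r}: {exc}") from exc
            logger.warning("dropping record %r: %s", rec.id, exc)
            continue
        out.append(
            NucleotideSequence(id=rec.id, bases=bases, description=rec.description)
        )
    if not out:
        warnings.warn(f"no usable records read from {path}", stacklevel=2)
    return out


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences to FASTA (round-trips exactly with :func:`read_fasta`)."""
    seq_records = [
        SeqRecord(Seq(r.bases), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` table (no header)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}"
            )
        seq_id, label = parts
        if label not in LOCALES:
            raise ValueError(
                f"{path}:{lineno}: unknown label {label!r}; "
                f"expected one of {LOCALES}"
            )
        if seq_id in mapping:
            raise ValueError(f"{path}:{lineno}: duplicate id {seq_id!r}")
        mapping[seq_id] = label
    return mapping


def write_label_table(records: Iterable[LabeledRecord], path: str | Path) -> None:
    lines = [f"{r.sequence.id}\t{r.label}" for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_labeled_dataset(
    fasta: str | Path | None = None,
    label_table: str | Path | None = None,
    per_locale_fasta: Mapping[str, str | Path] | None = None,
    policy: AmbiguousPolicy = "reject",
) -> list[LabeledRecord]:
    """Assemble a labeled dataset from FASTA input.

    Two input layouts are supported:

    * one FASTA plus an ``id<TAB>label`` table (``fasta`` + ``label_table``);
    * one FASTA per locale (``per_locale_fasta``, mapping locale -> path).

    Every sequence receives exactly one of the five locales; per-class
    counts are logged.
    """
    if per_locale_fasta is not None:
        if fasta is not None or label_table is not None:
            raise ValueError("pass either per_locale_fasta or fasta+label_table")
        records: list[LabeledRecord] = []
        for label, path in per_locale_fasta.items():
            if label not in LOCALES:
                raise ValueError(
                    f"unknown label {label!r}; expected one of {LOCALES}"
                )
            for seq in read_fasta(path, policy=policy):
                records.append(LabeledRecord(sequence=seq, label=label))
    else:
        if fasta is None or label_table is None:
            raise ValueError("both fasta and label_table are required")
        seqs = read_fasta(fasta, policy=policy)
        mapping = read_label_table(label_table)
        by_id = {s.id: s for s in seqs}
        missing = sorted(set(mapping) - set(by_id))
        if missing:
            raise ValueError(
                f"ids in label table missing from FASTA: {', '.join(missing)}"
            )
        records = [
            LabeledRecord(sequence=by_id[i], label=lab)
            for i, lab in mapping.items()
        ]

    ids = [r.sequence.id for r in records]
    dup = [i for i, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate sequence ids across inputs: {dup}")
    counts = Counter(r.label for r in records)
    logger.info("labeled dataset: %s", dict(counts))
    return records
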