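"""Reading, validation and normalization of miRNA / 3'UTR sequence records.

Sequences are handled as RNA (``ACGU``), 5'->3'.  DNA input (``T``) and
mixed case are accepted and normalized; anything else is rejected with a
:class:`ValidationError` that names the offending position.  Labeled
miRNA:gene pair tables are tab-delimited with optional binding-site
intervals given 0-based, half-open, on the supplied UTR sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .errors import ParseError, ValidationError

RNA_ALPHABET = frozenset("ACGU")

#: Encoding capacity for a mature miRNA; longer records are rejected.
MAX_MIRNA_LEN = 30


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence record (5'->3', RNA alphabet, <= 30 nt)."""

    id: str
    seq: str
    family: str | None = None

    def __post_init__(self) -> None:
        _check_rna(self.seq, where=self.id)
        if len(self.seq) > MAX_MIRNA_LEN:
            raise ValidationError(
                f"miRNA {self.id!r} is {len(self.seq)} nt; the fixed encoding "
                f"accommodates at most {MAX_MIRNA_LEN} nt"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneUTR:
    """A gene 3'UTR sequence record (5'->3', RNA alphabet)."""

    gene_id: str
    seq: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        _check_rna(self.seq, where=self.gene_id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LabeledPair:
    """A labeled miRNA:gene interaction, optionally with site intervals.

    ``sites`` intervals are 0-based half-open offsets on the UTR sequence.
    """

    mirna_id: str
    gene_id: str
    label: Literal["positive", "negative"]
    sites: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValidationError(f"label must be positive/negative, got {self.label!r}")
        for start, end in self.sites:
            if start < 0 or end <= start:
                raise ValidationError(
                    f"bad site interval [{start}, {end}) for pair "
                    f"({self.mirna_id}, {self.gene_id})"
                )


def _check_rna(seq: str, where: str = "sequence") -> None:
    if not seq:
        raise ValidationError(f"{where}: empty sequence")
    for i, c in enumerate(seq):
        if c not in RNA_ALPHABET:
            raise ValidationError(
                f"{where}: invalid character {c!r} at position {i + 1}; "
                "expected A/C/G/U"
            )


def normalize_rna(raw: str) -> str:
    """Uppercase, map T->U, and validate against the RNA alphabet.

    Idempotent; raises :class:`ValidationError` naming the first bad position.
    """
    if not raw:
        raise ValidationError("empty sequence")
    seq = raw.strip().upper().replace("T", "U")
    _check_rna(seq)
    return seq


def read_fasta(path: str | Path, kind: Literal["mirna", "utr"]) -> list:
    """Read a FASTA file into :class:`MatureMiRNA` or :class:`GeneUTR` records.

    Order is preserved; sequences are normalized via :func:`normalize_rna`.
    miRNA records longer than 30 nt are rejected rather than truncated.
    """
    if kind not in ("mirna", "utr"):
        raise ValueError(f"kind must be 'mirna' or 'utr', got {kind!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_rna(str(rec.seq))
        except ValidationError as exc:
            raise ValidationError(f"record {rec.id!r}: {exc}") from exc
        if kind == "mirna":
            records.append(MatureMiRNA(id=rec.id, seq=seq))
        else:
            records.append(GeneUTR(gene_id=rec.id, seq=seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write miRNA/UTR records back to FASTA (round-trip counterpart)."""
    with open(path, "w") as fh:
        for rec in records:
            name = rec.id if isinstance(rec, MatureMiRNA) else rec.gene_id
            fh.write(f">{name}\n{rec.seq}\n")


PAIR_TABLE_COLUMNS = ("mirna_id", "gene_id", "label", "sites")


def read_labeled_pairs(
    path: str | Path,
    utrs: dict[str, GeneUTR] | None = None,
) -> list[LabeledPair]:
    """Read a tab-delimited labeled-pair table.

    Columns: ``mirna_id  gene_id  label  [sites]`` where ``sites`` is an
    optional comma-separated list of ``start-end`` intervals (0-based,
    half-open).  A header line starting with ``mirna_id`` is skipped.
    Duplicate (mirna, gene) rows with conflicting labels are dropped with a
    warning; pairs validated under both labels carry no usable signal.
    When ``utrs`` is given, intervals are bounds-checked against it.
    """
    rows: list[LabeledPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n").rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "mirna_id":
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            mirna_id, gene_id, label = fields[0], fields[1], fields[2].lower()
            if label not in ("positive", "negative"):
                raise ParseError(f"{path}:{lineno}: unknown label token {fields[2]!r}")
            sites: tuple[tuple[int, int], ...] = ()
            if len(fields) > 3 and fields[3]:
                try:
                    sites = tuple(
                        (int(p.split("-")[0]), int(p.split("-")[1]))
                        for p in fields[3].split(",")
                    )
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed site list") from exc
            pair = LabeledPair(mirna_id=mirna_id, gene_id=gene_id, label=label, sites=sites)
            if utrs is not None and pair.sites:
                utr = utrs.get(gene_id)
                if utr is None:
                    raise ValidationError(f"{path}:{lineno}: unknown gene {gene_id!r}")
                for start, end in pair.sites:
                    if end > len(utr):
                        raise ValidationError(
                            f"{path}:{lineno}: interval [{start}, {end}) exceeds "
                            f"UTR length {len(utr)} for {gene_id}"
                        )
            rows.append(pair)

    # Drop pairs reported under both labels ("inconsistent entries").
    labels_by_pair: dict[tuple[str, str], set[str]] = {}
    for p in rows:
        labels_by_pair.setdefault((p.mirna_id, p.gene_id), set()).add(p.label)
    conflicting = {k for k, v in labels_by_pair.items() if len(v) > 1}
    if conflicting:
        warnings.warn(
            f"dropping {len(conflicting)} pair(s) with conflicting labels: "
            + ", ".join(f"{m}:{g}" for m, g in sorted(conflicting)),
            stacklevel=2,
        )
    kept: list[LabeledPair] = []
    seen: set[tuple[str, str]] = set()
    for p in rows:
        key = (p.mirna_id, p.gene_id)
        if key in conflicting or key in seen:
            continue
        seen.add(key)
        kept.append(p)
    return kept


def write_labeled_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_TABLE_COLUMNS) + "\n")
        for p in pairs:
            sites = ",".join(f"{s}-{e}" for s, e in p.sites)
            fh.write(f"{p.mirna_id}\t{p.gene_id}\t{p.label}\t{sites}\n")
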