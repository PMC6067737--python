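"""Duplex cofolding, base-pair classification and site-accessibility energy.

All folding goes through a pluggable :class:`FoldingBackend`:

* ``reference`` — the ViennaRNA engine (RNAcofold-style dimer MFE, and
  constrained/unconstrained ensemble free energies for accessibility).
* ``toy`` — a deterministic pair-counting model (each Watson-Crick pair
  -1.0 kcal/mol, each G:U wobble -0.5, no intramolecular structure) used by
  the test suite and anywhere an exactly enumerable oracle is needed.

Energies are kcal/mol throughout.  The site-accessibility energy is the
difference between the unconstrained ensemble free energy and the ensemble
free energy with the site forced single-stranded::

    dG_open = E(ensemble) - E(ensemble | site unpaired)   <= 0

Forcing nucleotides open can only remove states, so under this convention
dG_open is never positive: strongly structured sites give large negative
values and the gene-level filter removes sites whose dG_open lies *above*
a threshold (default -10 kcal/mol).  The convention is recorded on every
:class:`AccessibilityResult` so a differently-signed convention can never
be silently mixed in.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Iterable, Literal

from .errors import BackendError, ParseError, ValidationError
from .seqio import GeneUTR, MatureMiRNA, RNA_ALPHABET

PairType = Literal["WC", "wobble", "none"]

_WC_PAIRS = {frozenset("AU"), frozenset("CG")}
_WOBBLE = frozenset("GU")

#: Sign convention identifier stored with every accessibility result.
DG_OPEN_CONVENTION = "unconstrained-minus-constrained"


def classify_pair(a: str, b: str) -> PairType:
    """Classify a nucleotide pair as Watson-Crick, G:U wobble, or none.

    Symmetric and total on {A,C,G,U}.
    """
    if a not in RNA_ALPHABET or b not in RNA_ALPHABET:
        raise ValidationError(f"invalid nucleotide pair ({a!r}, {b!r})")
    key = frozenset((a, b))
    if key in _WC_PAIRS:
        return "WC"
    if key == _WOBBLE:
        return "wobble"
    return "none"


@dataclass(frozen=True)
class Pair:
    """One intermolecular base pair: 1-based miRNA and site positions."""

    mirna_pos: int
    site_pos: int
    pair_type: Literal["WC", "wobble"]


@dataclass(frozen=True)
class DuplexStructure:
    """Intermolecular pair map of a miRNA:site duplex plus its free energy."""

    pairs: frozenset[Pair]
    dg_duplex: float

    def __post_init__(self) -> None:
        mp = [p.mirna_pos for p in self.pairs]
        sp = [p.site_pos for p in self.pairs]
        if len(set(mp)) != len(mp) or len(set(sp)) != len(sp):
            raise ValidationError("a position participates in more than one pair")

    @property
    def mirna_positions(self) -> frozenset[int]:
        return frozenset(p.mirna_pos for p in self.pairs)

    def wc_positions(self) -> frozenset[int]:
        return frozenset(p.mirna_pos for p in self.pairs if p.pair_type == "WC")


@dataclass(frozen=True)
class AccessibilityResult:
    """Site-accessibility energy and the context it was computed over."""

    dg_open: float
    context_len: int
    convention: str = DG_OPEN_CONVENTION


# --------------------------------------------------------------------------
# dot-bracket plumbing


def parse_joint_structure(struct: str, strand1_len: int) -> set[tuple[int, int]]:
    """Decode a two-strand dot-bracket string into intermolecular pairs.

    ``struct`` uses ``&`` as the strand separator.  Returned pairs are
    per-strand 1-based ``(pos_in_strand1, pos_in_strand2)``; pairs with both
    ends in the same strand are excluded (they are not binding contacts).
    """
    if struct.count("&") != 1:
        raise ParseError("expected exactly one '&' strand separator")
    flat = struct.replace("&", "")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, c in enumerate(flat, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            if j <= strand1_len < i:
                pairs.add((j, i - strand1_len))
        elif c != ".":
            raise ParseError(f"invalid structure character {c!r}")
    if stack:
        raise ParseError("unbalanced '(' in structure")
    return pairs


def serialize_joint_structure(
    pairs: Iterable[tuple[int, int]], strand1_len: int, strand2_len: int
) -> str:
    """Inverse of :func:`parse_joint_structure` for intermolecular-only sets.

    Valid only when the pair set is nested (antiparallel helix ordering).
    """
    s1 = ["."] * strand1_len
    s2 = ["."] * strand2_len
    for p1, p2 in pairs:
        if not (1 <= p1 <= strand1_len and 1 <= p2 <= strand2_len):
            raise ValidationError(f"pair ({p1}, {p2}) out of range")
        s1[p1 - 1] = "("
        s2[p2 - 1] = ")"
    return "".join(s1) + "&" + "".join(s2)


# --------------------------------------------------------------------------
# backends


class FoldingBackend(ABC):
    """Contract every folding engine must satisfy."""

    name: str

    @abstractmethod
    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        """Joint MFE structure of two strands.

        Returns ``(dot_bracket_with_&, energy_kcal_mol)``.
        """

    @abstractmethod
    def ensemble_energy(self, seq: str, unpaired: tuple[int, int] | None = None) -> float:
        """Ensemble free energy of one strand, kcal/mol.

        ``unpaired`` is an optional 0-based half-open interval forced
        single-stranded (hard constraint).
        """


class ToyBackend(FoldingBackend):
    """Pair-counting duplex model with no intramolecular structure.

    The MFE joint structure is the best *ungapped antiparallel alignment* of
    the two strands; each WC pair contributes -1.0 and each G:U wobble -0.5.
    A single strand has zero structure, so every accessibility energy is 0.
    Exists so the full pipeline runs deterministically with an exhaustively
    checkable energy model.
    """

    name = "toy"
    WC_ENERGY = -1.0
    WOBBLE_ENERGY = -0.5

    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        if not seq_a or not seq_b:
            raise ValidationError("cofold requires two non-empty sequences")
        la, lb = len(seq_a), len(seq_b)
        rb = seq_b[::-1]
        best_energy = 0.0
        best_pairs: list[tuple[int, int]] = []
        # offset k aligns seq_a[i] with reversed(seq_b)[i+k]
        for k in range(-(la - 1), lb):
            energy = 0.0
            pairs: list[tuple[int, int]] = []
            for i in range(la):
                j = i + k
                if 0 <= j < lb:
                    pt = classify_pair(seq_a[i], rb[j])
                    if pt == "WC":
                        energy += self.WC_ENERGY
                    elif pt == "wobble":
                        energy += self.WOBBLE_ENERGY
                    else:
                        continue
                    pairs.append((i + 1, lb - j))  # back to seq_b 1-based
            if energy < best_energy:
                best_energy = energy
                best_pairs = pairs
        struct = serialize_joint_structure(best_pairs, la, lb)
        return struct, best_energy

    def ensemble_energy(self, seq: str, unpaired: tuple[int, int] | None = None) -> float:
        if not seq:
            raise ValidationError("empty sequence")
        return 0.0


class ViennaBackend(FoldingBackend):
    """Adapter over the ViennaRNA package (RNAcofold / constrained RNAfold)."""

    name = "reference"

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise BackendError(
                "the 'reference' backend requires the ViennaRNA Python bindings "
                "(module 'RNA'); install ViennaRNA or select the 'toy' backend"
            ) from exc
        self._rna = __import__("RNA")

    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        if not seq_a or not seq_b:
            raise ValidationError("cofold requires two non-empty sequences")
        struct, energy = self._rna.cofold(f"{seq_a}&{seq_b}")
        # ViennaRNA returns the concatenated structure without the separator.
        struct = struct[: len(seq_a)] + "&" + struct[len(seq_a):]
        return struct, float(energy)

    def ensemble_energy(self, seq: str, unpaired: tuple[int, int] | None = None) -> float:
        if not seq:
            raise ValidationError("empty sequence")
        fc = self._rna.fold_compound(seq)
        if unpaired is not None:
            start, end = unpaired
            for pos in range(start + 1, end + 1):  # ViennaRNA is 1-based
                fc.hc_add_up(pos)
        _, energy = fc.pf()
        return float(energy)


def get_backend(name: str) -> FoldingBackend:
    """Look up a folding backend by config name (``reference`` or ``toy``)."""
    if name == "toy":
        return ToyBackend()
    if name == "reference":
        return ViennaBackend()
    raise ValidationError(f"unknown thermo backend {name!r}; expected reference|toy")


# --------------------------------------------------------------------------
# operations


def cofold_duplex(
    mirna: MatureMiRNA | str, site_seq: str, backend: FoldingBackend
) -> DuplexStructure:
    """Predict the miRNA:site joint MFE structure and classify its pairs.

    Only intermolecular contacts are kept; intramolecular structure is not a
    binding contact and never counts toward seed-pair tallies.
    """
    mseq = mirna.seq if isinstance(mirna, MatureMiRNA) else mirna
    if not site_seq or len(site_seq) > 30:
        raise ValidationError(f"site must be 1..30 nt, got {len(site_seq)}")
    struct, energy = backend.cofold(mseq, site_seq)
    raw = parse_joint_structure(struct, len(mseq))
    pairs = set()
    for mpos, spos in raw:
        pt = classify_pair(mseq[mpos - 1], site_seq[spos - 1])
        if pt == "none":
            # A backend may pair non-complementary bases only by error.
            raise BackendError(
                f"backend {backend.name!r} paired non-complementary bases "
                f"{mseq[mpos - 1]}:{site_seq[spos - 1]} at ({mpos}, {spos})"
            )
        pairs.add(Pair(mirna_pos=mpos, site_pos=spos, pair_type=pt))
    return DuplexStructure(pairs=frozenset(pairs), dg_duplex=energy)


def delta_g_open(
    utr: GeneUTR | str,
    site_start: int,
    site_len: int,
    backend: FoldingBackend,
    context: int = 200,
) -> AccessibilityResult:
    """Site-accessibility energy over a local sequence context.

    The fold is computed on up to ``context`` nt centered on the site
    (default 200, truncated at UTR boundaries — flanking sequence is never
    fabricated).  Values within 1e-6 of zero are snapped to 0.0 so that a
    structure-free context reports exactly no opening cost.
    """
    seq = utr.seq if isinstance(utr, GeneUTR) else utr
    if site_len < 1 or site_start < 0 or site_start + site_len > len(seq):
        raise ValidationError(
            f"site [{site_start}, {site_start + site_len}) outside UTR of length {len(seq)}"
        )
    if context < site_len:
        raise ValidationError("context must be at least the site length")
    ext = (context - site_len) // 2
    ctx_start = max(0, site_start - ext)
    ctx_end = min(len(seq), site_start + site_len + ext)
    ctx_seq = seq[ctx_start:ctx_end]
    local = (site_start - ctx_start, site_start - ctx_start + site_len)
    e_free = backend.ensemble_energy(ctx_seq)
    e_open = backend.ensemble_energy(ctx_seq, unpaired=local)
    dg = e_free - e_open
    if abs(dg) < 1e-6:
        dg = 0.0
    return AccessibilityResult(dg_open=dg, context_len=len(ctx_seq))
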