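"""One-hot binarization of miRNA / extended-site transcripts.

Each nucleotide maps to a 4-bit code (A=0001, C=0010, G=0100, U=1000;
empty positions are all-zero).  A classifier input is the concatenation of

* a 120-bit miRNA vector — 30 slots, 5'->3', left-aligned so the seed
  always occupies the same input nodes (30 slots fit the longest known
  mature miRNA), and
* a 160-bit extended-site vector — 40 slots laid out as
  ``[5 upstream flank][30 site][5 downstream flank]`` in mRNA 5'->3'
  orientation; boundary-truncated flanks leave their slots empty, so the
  first site nucleotide always lands on the same bit index.

Total input dimension: 280.  ``ENCODING_VERSION`` travels with every saved
model so weights trained under one layout are never applied to another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .seqio import MatureMiRNA

ENCODING_VERSION = "one-hot/v1"

MIRNA_CAPACITY = 30
SITE_CAPACITY = 30
FLANK_CAPACITY = 5
SITE_FRAME = FLANK_CAPACITY + SITE_CAPACITY + FLANK_CAPACITY  # 40 slots

MIRNA_DIM = 4 * MIRNA_CAPACITY        # 120
SITE_DIM = 4 * SITE_FRAME             # 160
PAIR_DIM = MIRNA_DIM + SITE_DIM       # 280

_CODE = {
    "A": (0, 0, 0, 1),
    "C": (0, 0, 1, 0),
    "G": (0, 1, 0, 0),
    "U": (1, 0, 0, 0),
    None: (0, 0, 0, 0),
}
_DECODE = {code: nt for nt, code in _CODE.items()}


def encode_nucleotide(n: str | None) -> np.ndarray:
    """4-bit code of one nucleotide (``None`` encodes an empty slot)."""
    try:
        return np.array(_CODE[n], dtype=np.uint8)
    except KeyError:
        raise ValidationError(f"cannot encode symbol {n!r}") from None


def encode_sequence(seq: str, capacity: int) -> np.ndarray:
    """Binarize ``seq`` into ``4 * capacity`` bits, empty-padded at the end."""
    if len(seq) > capacity:
        raise ValidationError(f"sequence of {len(seq)} nt exceeds capacity {capacity}")
    bits = np.zeros(4 * capacity, dtype=np.uint8)
    for i, nt in enumerate(seq):
        bits[4 * i:4 * i + 4] = encode_nucleotide(nt)
    return bits


def decode_sequence(bits: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` on the non-empty prefix."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.ndim != 1 or bits.size % 4:
        raise ValidationError("bit vector length must be a multiple of 4")
    out: list[str] = []
    ended = False
    for i in range(0, bits.size, 4):
        block = tuple(int(b) for b in bits[i:i + 4])
        if block not in _DECODE:
            raise ValidationError(f"invalid 4-bit block {block} at slot {i // 4}")
        nt = _DECODE[block]
        if nt is None:
            ended = True
        elif ended:
            raise ValidationError(f"non-empty slot {i // 4} after an empty slot")
        else:
            out.append(nt)
    return "".join(out)


def encode_site(site_seq: str, up_flank: str = "", down_flank: str = "") -> np.ndarray:
    """Binarize an extended site into the fixed 40-slot frame (160 bits)."""
    if len(site_seq) > SITE_CAPACITY:
        raise ValidationError(f"site of {len(site_seq)} nt exceeds {SITE_CAPACITY}")
    if len(up_flank) > FLANK_CAPACITY or len(down_flank) > FLANK_CAPACITY:
        raise ValidationError(f"flanks may be at most {FLANK_CAPACITY} nt")
    bits = np.zeros(SITE_DIM, dtype=np.uint8)
    # upstream flank sits right-aligned against the site start
    for i, nt in enumerate(up_flank):
        slot = FLANK_CAPACITY - len(up_flank) + i
        bits[4 * slot:4 * slot + 4] = encode_nucleotide(nt)
    for i, nt in enumerate(site_seq):
        slot = FLANK_CAPACITY + i
        bits[4 * slot:4 * slot + 4] = encode_nucleotide(nt)
    for i, nt in enumerate(down_flank):
        slot = FLANK_CAPACITY + SITE_CAPACITY + i
        bits[4 * slot:4 * slot + 4] = encode_nucleotide(nt)
    return bits


@dataclass(frozen=True)
class EncodedPair:
    """The 280-bit network input for one (miRNA, extended site) pair."""

    mirna_bits: np.ndarray  # 120
    site_bits: np.ndarray   # 160

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.mirna_bits, self.site_bits])


def encode_pair(
    mirna: MatureMiRNA | str,
    site_seq: str,
    up_flank: str = "",
    down_flank: str = "",
) -> EncodedPair:
    """Build the concatenated one-hot input for one miRNA:site pair."""
    mseq = mirna.seq if isinstance(mirna, MatureMiRNA) else mirna
    return EncodedPair(
        mirna_bits=encode_sequence(mseq, MIRNA_CAPACITY),
        site_bits=encode_site(site_seq, up_flank, down_flank),
    )
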