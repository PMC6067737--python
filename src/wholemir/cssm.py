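"""Candidate-site selection: sliding-window UTR scan plus acceptance rules.

A 30 nt window slides along the 3'UTR in 5 nt steps.  Each window is
cofolded with the miRNA; windows forming a stable duplex (negative free
energy) are then tested against a candidate-site selection method (CSSM).
Five CSSMs are provided:

* ``6-1:10`` — at least 6 base pairs (WC or G:U wobble) at miRNA
  positions 1..10;
* ``7-1:10`` — at least 7 pairs at positions 1..10;
* ``7-2:10`` — at least 7 pairs at positions 2..10;
* ``targetscan`` — canonical perfect seed (WC at 2..8), 3'-compensatory
  (one seed defect offset by >= 3 consecutive WC pairs in 13..16), or
  centered (11 contiguous WC pairs within 4..15);
* ``pita`` — perfect 7mer at 1..7 or 2..8, or a single seed defect with
  at least 7 WC pairs over positions 1..8.

Pairs need not be consecutive for the extended-seed rules, accommodating
gaps and bulges.  A seed position with no intermolecular pair counts as a
defect; a G:U pair is a defect for clauses demanding Watson-Crick pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .errors import ValidationError
from .seqio import GeneUTR, MatureMiRNA
from .thermo import DuplexStructure, FoldingBackend, cofold_duplex

WINDOW = 30
STEP = 5
FLANK = 5


@dataclass(frozen=True)
class CSSMConfig:
    """One candidate-site selection rule."""

    name: str
    kind: Literal["extended_seed", "targetscan", "pita"]
    region_start: int = 0
    region_end: int = 0
    min_pairs: int = 0

    def __post_init__(self) -> None:
        if self.kind == "extended_seed":
            if not (1 <= self.region_start <= self.region_end <= 10):
                raise ValidationError("extended-seed region must lie within 1..10")
            width = self.region_end - self.region_start + 1
            if not (1 <= self.min_pairs <= width):
                raise ValidationError("min_pairs must be within the region width")

    def accepts(self, duplex: DuplexStructure) -> bool:
        if self.kind == "extended_seed":
            return accept_extended_seed(duplex, self)
        if self.kind == "targetscan":
            return accept_targetscan(duplex)
        return accept_pita(duplex)


CSSM_PRESETS: dict[str, CSSMConfig] = {
    "6-1:10": CSSMConfig("6-1:10", "extended_seed", 1, 10, 6),
    "7-1:10": CSSMConfig("7-1:10", "extended_seed", 1, 10, 7),
    "7-2:10": CSSMConfig("7-2:10", "extended_seed", 2, 10, 7),
    "targetscan": CSSMConfig("targetscan", "targetscan"),
    "pita": CSSMConfig("pita", "pita"),
}


def get_cssm(name: str) -> CSSMConfig:
    try:
        return CSSM_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown CSSM {name!r}; expected one of {sorted(CSSM_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SiteWindow:
    """One scanned UTR window with its real (never fabricated) flanks."""

    start: int
    site_seq: str
    up_flank: str
    down_flank: str

    @property
    def extended_seq(self) -> str:
        return self.up_flank + self.site_seq + self.down_flank


@dataclass(frozen=True)
class CandidateSite:
    """A window accepted by at least one CSSM, with its duplex structure."""

    gene_id: str
    window_start: int
    site_seq: str
    up_flank: str
    down_flank: str
    duplex: DuplexStructure
    accepted_by: frozenset[str] = field(default_factory=frozenset)

    @property
    def extended_seq(self) -> str:
        return self.up_flank + self.site_seq + self.down_flank

    @property
    def canonical(self) -> bool:
        """Perfect WC seed pairing at miRNA positions 2..8."""
        wc = self.duplex.wc_positions()
        return all(p in wc for p in range(2, 9))


def scan_windows(
    utr: GeneUTR, window: int = WINDOW, step: int = STEP, flank: int = FLANK
) -> list[SiteWindow]:
    """Slide a window along the UTR, attaching up to ``flank`` nt of context.

    Windows start at 0, step, 2*step, ... while they fit.  A UTR shorter
    than the window yields a single whole-UTR window (refusing to scan
    short UTRs would silently drop genes).  Flanks are truncated, never
    padded, at UTR boundaries.
    """
    if window < 1 or step < 1:
        raise ValidationError("window and step must be >= 1")
    seq = utr.seq
    if not seq:
        raise ValidationError(f"{utr.gene_id}: empty UTR")
    starts = list(range(0, len(seq) - window + 1, step)) if len(seq) >= window else [0]
    out = []
    for s in starts:
        e = min(s + window, len(seq))
        out.append(
            SiteWindow(
                start=s,
                site_seq=seq[s:e],
                up_flank=seq[max(0, s - flank):s],
                down_flank=seq[e:e + flank],
            )
        )
    return out


def count_region_pairs(duplex: DuplexStructure, region_start: int, region_end: int) -> int:
    """Number of miRNA positions in [region_start, region_end] that pair.

    Both WC and wobble pairs count; pairs need not be consecutive.
    """
    if not (1 <= region_start <= region_end):
        raise ValidationError("need 1 <= region_start <= region_end")
    return sum(1 for p in duplex.mirna_positions if region_start <= p <= region_end)


def accept_extended_seed(duplex: DuplexStructure, cfg: CSSMConfig) -> bool:
    if cfg.kind != "extended_seed":
        raise ValidationError(f"{cfg.name} is not an extended-seed CSSM")
    return count_region_pairs(duplex, cfg.region_start, cfg.region_end) >= cfg.min_pairs


def _has_wc_run(wc: frozenset[int], lo: int, hi: int, run: int) -> bool:
    """True iff >= ``run`` consecutive WC-paired positions lie within [lo, hi]."""
    streak = 0
    for p in range(lo, hi + 1):
        streak = streak + 1 if p in wc else 0
        if streak >= run:
            return True
    return False


def accept_targetscan(duplex: DuplexStructure) -> bool:
    wc = duplex.wc_positions()
    # (i) canonical: perfect WC complementarity across the seed (2..8)
    if all(p in wc for p in range(2, 9)):
        return True
    # (ii) 3' compensatory: exactly one seed defect (wobble, bulge or
    # mismatch) offset by >= 3 consecutive WC pairs within 13..16
    defects = sum(1 for p in range(2, 9) if p not in wc)
    if defects == 1 and _has_wc_run(wc, 13, 16, 3):
        return True
    # (iii) centered: 11 contiguous WC pairs within 4..15
    return _has_wc_run(wc, 4, 15, 11)


def accept_pita(duplex: DuplexStructure) -> bool:
    wc = duplex.wc_positions()
    # (i) perfect 7mer starting at nt 1 or nt 2
    if all(p in wc for p in range(1, 8)) or all(p in wc for p in range(2, 9)):
        return True
    # (ii) one gap/wobble/mismatch in the seed region starting at nt 1,
    # still holding >= 7 WC pairs over that region (positions 1..8)
    defects = sum(1 for p in range(1, 9) if p not in wc)
    n_wc = sum(1 for p in range(1, 9) if p in wc)
    return defects == 1 and n_wc >= 7


def select_candidate_sites(
    mirna: MatureMiRNA,
    utr: GeneUTR,
    cssm: CSSMConfig | str,
    backend: FoldingBackend,
    window: int = WINDOW,
    step: int = STEP,
) -> list[CandidateSite]:
    """Scan a UTR and return the candidate sites for one miRNA.

    Per window: cofold with the miRNA; keep the window only if the duplex
    has strictly negative free energy, and only if its pair map satisfies
    the chosen CSSM.  Overlapping accepted windows are kept as distinct
    candidates (the 5 nt step already keeps redundancy minimal).  The
    ``accepted_by`` field records every preset rule the window satisfies.
    """
    if isinstance(cssm, str):
        cssm = get_cssm(cssm)
    sites: list[CandidateSite] = []
    for win in scan_windows(utr, window=window, step=step):
        duplex = cofold_duplex(mirna, win.site_seq, backend)
        if duplex.dg_duplex >= 0:  # the stability gate is strict
            continue
        if not cssm.accepts(duplex):
            continue
        accepted = frozenset(
            name for name, cfg in CSSM_PRESETS.items() if cfg.accepts(duplex)
        )
        sites.append(
            CandidateSite(
                gene_id=utr.gene_id,
                window_start=win.start,
                site_seq=win.site_seq,
                up_flank=win.up_flank,
                down_flank=win.down_flank,
                duplex=duplex,
                accepted_by=accepted,
            )
        )
    return sites


def write_candidate_table(sites: Iterable[CandidateSite], path) -> None:
    """Export candidate sites as a BED-like tab table."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tcssm\tdg_duplex\n")
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{s.window_start}\t{s.window_start + len(s.site_seq)}\t"
                f"{','.join(sorted(s.accepted_by))}\t{s.duplex.dg_duplex:.2f}\n"
            )
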