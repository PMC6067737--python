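"""Site-level training data, cross-validation folds, synthetic corpora.

Site examples are miRNA:binding-site pairs (not miRNA:gene pairs): the
classifier is trained on 30 nt site windows with their real UTR flanks.
Negative examples are mined by sliding a window over the UTR of a
negatively-validated pair and keeping every window that cofolds with the
miRNA at negative free energy; positive examples come from annotated site
intervals subject to the same stability gate.

Cross-validation follows a random-subsampling scheme: each fold draws an
independent ~66.67% training sample, stratified so each sampled miRNA
family contributes both classes where possible, and the held-out remainder
is purged of any example sharing a miRNA family or an exact site sequence
with that fold's training sample before being used for validation/testing.

The synthetic generator emulates the shape of CLIP/CLASH-derived training
corpora: random miRNAs grouped into seed-sharing families, random UTRs,
and planted binding sites built from the miRNA's reverse complement with a
controlled pairing profile — positives satisfy the generating grammar
(extended seed, optionally with wobbles, plus 3' compensatory pairing),
negatives are near-misses that still form stable duplexes but violate the
seed requirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cssm import CSSMConfig, FLANK, WINDOW, get_cssm, scan_windows
from .encode import encode_pair
from .errors import ValidationError
from .seqio import GeneUTR, LabeledPair, MatureMiRNA
from .thermo import FoldingBackend, classify_pair, cofold_duplex

# fold role codes
TRAIN, TEST, EXCLUDED = 0, 1, 2
ROLE_NAMES = {TRAIN: "train", TEST: "test", EXCLUDED: "excluded"}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_ALPHABET = "ACGU"


@dataclass(frozen=True)
class SiteExample:
    """One labeled miRNA:site training example."""

    mirna_id: str
    gene_id: str
    window_start: int
    site_seq: str
    up_flank: str
    down_flank: str
    label: int  # +1 / -1
    provenance: str  # annotated_site | mined_window | synthetic

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise ValidationError("label must be +1 or -1")
        if len(self.site_seq) > WINDOW or len(self.up_flank) > FLANK or len(self.down_flank) > FLANK:
            raise ValidationError("site/flank lengths exceed the encoding frame")

    @property
    def extended_seq(self) -> str:
        return self.up_flank + self.site_seq + self.down_flank


@dataclass
class FoldPlan:
    """Random-subsampling cross-validation layout."""

    n_folds: int = 10
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    #: per fold, an int array of role codes (TRAIN / TEST / EXCLUDED)
    assignments: list[np.ndarray] = field(default_factory=list)


def _index_by_id(mirnas: Iterable[MatureMiRNA], utrs: Iterable[GeneUTR]):
    m = {r.id: r for r in mirnas}
    u = {r.gene_id: r for r in utrs}
    return m, u


def _require_ids(pairs: Sequence[LabeledPair], mirnas: dict, utrs: dict) -> None:
    missing = sorted(
        {p.mirna_id for p in pairs if p.mirna_id not in mirnas}
        | {p.gene_id for p in pairs if p.gene_id not in utrs}
    )
    if missing:
        raise ValidationError(f"missing sequences for ids: {', '.join(missing)}")


def build_negative_sites(
    pairs: Sequence[LabeledPair],
    mirnas: Iterable[MatureMiRNA],
    utrs: Iterable[GeneUTR],
    backend: FoldingBackend,
) -> list[SiteExample]:
    """Mine negative site examples from negatively-validated pairs.

    Every 30 nt window (5 nt step) of the pair's UTR whose duplex with the
    miRNA has strictly negative free energy becomes one negative example.
    """
    mirna_by_id, utr_by_id = _index_by_id(mirnas, utrs)
    _require_ids(pairs, mirna_by_id, utr_by_id)
    out: list[SiteExample] = []
    for pair in pairs:
        if pair.label != "negative":
            raise ValidationError(f"pair ({pair.mirna_id}, {pair.gene_id}) is not negative")
        mirna = mirna_by_id[pair.mirna_id]
        utr = utr_by_id[pair.gene_id]
        for win in scan_windows(utr):
            duplex = cofold_duplex(mirna, win.site_seq, backend)
            if duplex.dg_duplex < 0:
                out.append(
                    SiteExample(
                        mirna_id=mirna.id,
                        gene_id=utr.gene_id,
                        window_start=win.start,
                        site_seq=win.site_seq,
                        up_flank=win.up_flank,
                        down_flank=win.down_flank,
                        label=-1,
                        provenance="mined_window",
                    )
                )
    return out


def build_positive_sites(
    pairs: Sequence[LabeledPair],
    mirnas: Iterable[MatureMiRNA],
    utrs: Iterable[GeneUTR],
    backend: FoldingBackend,
    cssm: CSSMConfig | str | None = None,
) -> list[SiteExample]:
    """Positive site examples from annotated intervals (stability-gated).

    Annotated sites failing the negative-free-energy check are dropped with
    a warning.  Pairs lacking site coordinates are handled by mining, as
    for negatives, but a window is labeled positive only if it satisfies
    the configured CSSM; such examples carry ``mined_window`` provenance so
    they can be excluded downstream.
    """
    mirna_by_id, utr_by_id = _index_by_id(mirnas, utrs)
    _require_ids(pairs, mirna_by_id, utr_by_id)
    if cssm is not None and isinstance(cssm, str):
        cssm = get_cssm(cssm)
    out: list[SiteExample] = []
    for pair in pairs:
        if pair.label != "positive":
            raise ValidationError(f"pair ({pair.mirna_id}, {pair.gene_id}) is not positive")
        mirna = mirna_by_id[pair.mirna_id]
        utr = utr_by_id[pair.gene_id]
        if pair.sites:
            for start, end in pair.sites:
                if end > len(utr):
                    raise ValidationError(
                        f"interval [{start}, {end}) outside UTR {utr.gene_id}"
                    )
                if end - start > WINDOW:
                    raise ValidationError(
                        f"annotated site [{start}, {end}) longer than {WINDOW} nt"
                    )
                site_seq = utr.seq[start:end]
                duplex = cofold_duplex(mirna, site_seq, backend)
                if duplex.dg_duplex >= 0:
                    warnings.warn(
                        f"dropping annotated site {utr.gene_id}:[{start}, {end}) for "
                        f"{mirna.id}: duplex not stable (dG = {duplex.dg_duplex:.2f})",
                        stacklevel=2,
                    )
                    continue
                out.append(
                    SiteExample(
                        mirna_id=mirna.id,
                        gene_id=utr.gene_id,
                        window_start=start,
                        site_seq=site_seq,
                        up_flank=utr.seq[max(0, start - FLANK):start],
                        down_flank=utr.seq[end:end + FLANK],
                        label=1,
                        provenance="annotated_site",
                    )
                )
        else:
            if cssm is None:
                raise ValidationError(
                    f"pair ({mirna.id}, {utr.gene_id}) has no site intervals; "
                    "pass a CSSM to mine candidate windows"
                )
            for win in scan_windows(utr):
                duplex = cofold_duplex(mirna, win.site_seq, backend)
                if duplex.dg_duplex < 0 and cssm.accepts(duplex):
                    out.append(
                        SiteExample(
                            mirna_id=mirna.id,
                            gene_id=utr.gene_id,
                            window_start=win.start,
                            site_seq=win.site_seq,
                            up_flank=win.up_flank,
                            down_flank=win.down_flank,
                            label=1,
                            provenance="mined_window",
                        )
                    )
    return out


# --------------------------------------------------------------------------
# cross-validation folds


def make_cv_folds(
    examples: Sequence[SiteExample],
    families: dict[str, str],
    plan: FoldPlan | None = None,
) -> FoldPlan:
    """Build random-subsampling folds with family-aware stratification.

    Per fold: ~``train_fraction`` of examples (within one example) are
    sampled for training, walking miRNA families in shuffled order and
    drawing both classes from each family against per-class quotas that
    preserve the global class ratio.  Families with a single class are
    confined to training (with a warning).  Held-out examples that share a
    miRNA family or an exact site sequence with the fold's training sample
    are marked EXCLUDED; the rest are TEST.  Deterministic given the seed.
    """
    plan = plan or FoldPlan()
    n = len(examples)
    if n == 0:
        raise ValidationError("no examples to fold")
    fams = []
    for ex in examples:
        if ex.mirna_id not in families:
            raise ValidationError(f"miRNA {ex.mirna_id!r} has no family mapping")
        fams.append(families[ex.mirna_id])
    fams = np.array(fams)
    labels = np.array([ex.label for ex in examples])
    sites = np.array([ex.site_seq for ex in examples])

    fam_names = sorted(set(fams.tolist()))
    single_class = [f for f in fam_names if len(set(labels[fams == f].tolist())) == 1]
    if single_class:
        warnings.warn(
            f"{len(single_class)} famil(ies) have a single class and are "
            "confined to training in every fold",
            stacklevel=2,
        )
    multi_class = [f for f in fam_names if f not in single_class]

    n_pos = int((labels == 1).sum())
    quota_total = int(round(plan.train_fraction * n))
    plan.assignments = []
    for fold in range(plan.n_folds):
        rng = np.random.default_rng([plan.seed, fold])
        roles = np.full(n, TEST, dtype=np.int8)
        quota_pos = int(round(quota_total * n_pos / n))
        quota_neg = quota_total - quota_pos

        train_idx: list[int] = []
        for f in single_class:
            idx = np.flatnonzero(fams == f)
            train_idx.extend(idx.tolist())
            taken_pos = int((labels[idx] == 1).sum())
            quota_pos = max(0, quota_pos - taken_pos)
            quota_neg = max(0, quota_neg - (len(idx) - taken_pos))

        for f in rng.permutation(multi_class):
            if quota_pos <= 0 and quota_neg <= 0:
                break
            idx = np.flatnonzero(fams == f)
            pos = rng.permutation(idx[labels[idx] == 1])
            neg = rng.permutation(idx[labels[idx] == -1])
            take_pos = pos[:quota_pos]
            take_neg = neg[:quota_neg]
            train_idx.extend(take_pos.tolist())
            train_idx.extend(take_neg.tolist())
            quota_pos -= len(take_pos)
            quota_neg -= len(take_neg)

        train_arr = np.array(sorted(train_idx), dtype=int)
        roles[train_arr] = TRAIN
        train_fams = set(fams[train_arr].tolist())
        train_sites = set(sites[train_arr].tolist())
        holdout = np.flatnonzero(roles != TRAIN)
        for i in holdout:
            if fams[i] in train_fams or sites[i] in train_sites:
                roles[i] = EXCLUDED
        plan.assignments.append(roles)
    return plan


def fold_indices(plan: FoldPlan, fold: int):
    """Convenience accessor: (train_idx, test_idx, excluded_idx) arrays."""
    roles = plan.assignments[fold]
    return (
        np.flatnonzero(roles == TRAIN),
        np.flatnonzero(roles == TEST),
        np.flatnonzero(roles == EXCLUDED),
    )


# --------------------------------------------------------------------------
# synthetic corpus generator


@dataclass(frozen=True)
class SyntheticGrammar:
    """Generative rule for planted binding sites.

    ``kind`` selects the positive-site grammar:

    * ``extended_seed_compensatory`` — positives pair at >= ``min_seed_pairs``
      of miRNA positions 1..10 (up to ``max_wobbles`` as G:U wobbles) and
      carry full WC pairing at positions 13..16 (3' compensation);
    * ``canonical`` — positives carry a perfect WC 7mer at positions 2..8.

    Negatives pair at most ``neg_max_seed_pairs`` seed positions but keep
    enough 3' pairing to form a stable duplex (near-misses, not random
    sequence).  ``label_noise`` flips each label independently.
    """

    kind: str = "extended_seed_compensatory"
    min_seed_pairs: int = 7
    max_wobbles: int = 2
    neg_max_seed_pairs: int = 5
    label_noise: float = 0.0
    mirna_len_range: tuple[int, int] = (18, 25)
    utr_len_range: tuple[int, int] = (100, 2000)
    n_mirnas: int | None = None
    family_size: int = 3

    def validate(self) -> None:
        if self.kind not in ("extended_seed_compensatory", "canonical"):
            raise ValidationError(f"unknown grammar kind {self.kind!r}")
        if not (0 <= self.label_noise <= 1):
            raise ValidationError("label_noise must be in [0, 1]")
        if not (1 <= self.min_seed_pairs <= 10) or not (0 <= self.neg_max_seed_pairs < self.min_seed_pairs):
            raise ValidationError("seed-pair counts must satisfy 0 <= neg < pos <= 10")


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _mismatch_nt(rng: np.random.Generator, mirna_nt: str) -> str:
    """A site nucleotide forming neither a WC nor a wobble pair."""
    options = [c for c in _ALPHABET if classify_pair(mirna_nt, c) == "none"]
    return options[rng.integers(len(options))]


def _wobble_nt(mirna_nt: str) -> str | None:
    if mirna_nt == "G":
        return "U"
    if mirna_nt == "U":
        return "G"
    return None


def _planted_region(
    rng: np.random.Generator, mirna: str, label: int, grammar: SyntheticGrammar
) -> str:
    """Build the complementary site region (5'->3' mRNA) for one example."""
    L = len(mirna)
    # pairing profile per 1-based miRNA position: "wc", "wobble" or "mis"
    profile = ["wc"] * L

    seed_positions = list(range(1, 11))
    if label == 1 and grammar.kind == "canonical":
        # perfect 7mer at 2..8; 1, 9, 10 free
        for p in (1, 9, 10):
            if rng.random() < 0.5:
                profile[p - 1] = "mis"
    elif label == 1:
        n_pairs = int(rng.integers(grammar.min_seed_pairs, 11))
        paired = rng.permutation(seed_positions)[:n_pairs]
        for p in seed_positions:
            if p not in paired:
                profile[p - 1] = "mis"
        wobblable = [p for p in paired if _wobble_nt(mirna[p - 1])]
        n_wob = int(rng.integers(0, grammar.max_wobbles + 1))
        for p in rng.permutation(wobblable)[:n_wob]:
            profile[p - 1] = "wobble"
    else:
        n_pairs = int(rng.integers(2, grammar.neg_max_seed_pairs + 1))
        paired = set(rng.permutation(seed_positions)[:n_pairs].tolist())
        for p in seed_positions:
            if p not in paired:
                profile[p - 1] = "mis"
        # near-miss 3' pairing: dense enough for a stable duplex but the
        # scattered density typical of mined (non-functional) windows
        for p in range(11, L + 1):
            if rng.random() >= 0.6:
                profile[p - 1] = "mis"
        region = list(_revcomp(mirna))
        for p in range(1, L + 1):
            j = L - p
            if profile[p - 1] == "mis":
                region[j] = _mismatch_nt(rng, mirna[p - 1])
        return "".join(region)

    # positives: positions 11..12 free
    for p in (11, 12):
        if p <= L and rng.random() < 0.5:
            profile[p - 1] = "mis"
    # 3' compensation region 13..16
    for p in range(13, 17):
        if p <= L:
            if grammar.kind == "extended_seed_compensatory":
                profile[p - 1] = "wc"
            elif rng.random() < 0.5:
                profile[p - 1] = "mis"
    # remaining 3' tail pairs most of the time
    for p in range(17, L + 1):
        if rng.random() >= 0.8:
            profile[p - 1] = "mis"

    region = list(_revcomp(mirna))
    for p in range(1, L + 1):
        j = L - p  # region index pairing miRNA position p (antiparallel)
        if profile[p - 1] == "mis":
            region[j] = _mismatch_nt(rng, mirna[p - 1])
        elif profile[p - 1] == "wobble":
            region[j] = _wobble_nt(mirna[p - 1]) or region[j]
    return "".join(region)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def generate_synthetic_dataset(
    n: int,
    grammar: SyntheticGrammar | None = None,
    seed: int = 0,
) -> tuple[list[MatureMiRNA], list[GeneUTR], list[LabeledPair], list[SiteExample]]:
    """Generate a balanced synthetic corpus of planted binding sites.

    Returns miRNAs (grouped into seed-sharing families), one UTR per
    example with the site window implanted on the 5 nt scanning grid,
    labeled pairs carrying the site interval, and the site-level examples.
    Classes alternate (n even -> exactly balanced) and every miRNA receives
    both labels across the corpus.  Fully deterministic given ``seed``.
    """
    if n < 2:
        raise ValidationError("need n >= 2")
    grammar = grammar or SyntheticGrammar()
    grammar.validate()
    rng = np.random.default_rng(seed)

    # ~12 site examples per miRNA, the density of CLIP/CLASH-derived corpora
    n_mirnas = grammar.n_mirnas or max(4, n // 12)
    mirnas: list[MatureMiRNA] = []
    fam = 0
    while len(mirnas) < n_mirnas:
        lo, hi = grammar.mirna_len_range
        base = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        for member in range(grammar.family_size):
            if len(mirnas) >= n_mirnas:
                break
            seq = list(base)
            if member > 0:  # family members share the extended seed (1..10)
                for pos in rng.choice(np.arange(10, len(base)), size=min(3, len(base) - 10), replace=False):
                    seq[pos] = _ALPHABET[rng.integers(4)]
            mirnas.append(
                MatureMiRNA(id=f"syn-mir-{len(mirnas):04d}", seq="".join(seq), family=f"fam-{fam:03d}")
            )
        fam += 1

    utrs: list[GeneUTR] = []
    pairs: list[LabeledPair] = []
    examples: list[SiteExample] = []
    for i in range(n):
        mirna = mirnas[(i // 2) % n_mirnas]
        label = 1 if i % 2 == 0 else -1
        region = _planted_region(rng, mirna.seq, label, grammar)
        L = len(region)
        # the duplex region is right-aligned in the window so the seed
        # complement always occupies the same input nodes, matching the
        # seed-aligned layout the classifier input assumes
        start_in_window = WINDOW - L
        window = (
            _random_seq(rng, start_in_window)
            + region
            + _random_seq(rng, WINDOW - start_in_window - L)
        )
        lo, hi = grammar.utr_len_range
        ulen = int(rng.integers(lo, hi + 1))
        pos = 5 * int(rng.integers(0, (ulen - WINDOW) // 5 + 1))
        useq = _random_seq(rng, pos) + window + _random_seq(rng, ulen - pos - WINDOW)
        gene_id = f"syn-gene-{i:05d}"
        utrs.append(GeneUTR(gene_id=gene_id, seq=useq))

        if grammar.label_noise > 0 and rng.random() < grammar.label_noise:
            label = -label
        pairs.append(
            LabeledPair(
                mirna_id=mirna.id,
                gene_id=gene_id,
                label="positive" if label == 1 else "negative",
                sites=((pos, pos + WINDOW),),
            )
        )
        examples.append(
            SiteExample(
                mirna_id=mirna.id,
                gene_id=gene_id,
                window_start=pos,
                site_seq=window,
                up_flank=useq[max(0, pos - FLANK):pos],
                down_flank=useq[pos + WINDOW:pos + WINDOW + FLANK],
                label=label,
                provenance="synthetic",
            )
        )
    return mirnas, utrs, pairs, examples


def family_map(mirnas: Iterable[MatureMiRNA]) -> dict[str, str]:
    """miRNA id -> family label (own id when no family is annotated)."""
    return {m.id: (m.family or m.id) for m in mirnas}


def encode_examples(
    examples: Sequence[SiteExample], mirnas: Iterable[MatureMiRNA]
) -> tuple[np.ndarray, np.ndarray]:
    """Binarize site examples into an (n, 280) matrix and a +1/-1 label vector."""
    by_id = {m.id: m for m in mirnas}
    X = np.zeros((len(examples), 280), dtype=np.uint8)
    y = np.zeros(len(examples), dtype=int)
    for i, ex in enumerate(examples):
        enc = encode_pair(by_id[ex.mirna_id], ex.site_seq, ex.up_flank, ex.down_flank)
        X[i] = enc.combined
        y[i] = ex.label
    return X, y


# --------------------------------------------------------------------------
# table IO

EXAMPLE_COLUMNS = (
    "mirna_id", "gene_id", "window_start", "site_seq",
    "up_flank", "down_flank", "label", "provenance",
)


def write_examples(examples: Iterable[SiteExample], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXAMPLE_COLUMNS) + "\n")
        for ex in examples:
            fh.write(
                f"{ex.mirna_id}\t{ex.gene_id}\t{ex.window_start}\t{ex.site_seq}\t"
                f"{ex.up_flank}\t{ex.down_flank}\t{ex.label:+d}\t{ex.provenance}\n"
            )


def read_examples(path) -> list[SiteExample]:
    out: list[SiteExample] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if tuple(header) != EXAMPLE_COLUMNS:
            raise ValidationError(f"{path}: unexpected example-table header")
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            f = line.split("\t")
            out.append(
                SiteExample(
                    mirna_id=f[0], gene_id=f[1], window_start=int(f[2]), site_seq=f[3],
                    up_flank=f[4], down_flank=f[5], label=int(f[6]), provenance=f[7],
                )
            )
    return out
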