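"""Gene-level target prediction: scan, score, filter, aggregate.

A miRNA is predicted to target a gene if at least one candidate binding
site survives the (optional) accessibility filter and is classified
positive by the network — the gene verdict is the disjunction of the
per-site calls.  Grey-area ("unknown") site calls never contribute to the
disjunction.  Because a single false-positive site flips the whole gene,
the chance of a spurious gene call grows with the number of candidate
sites as ``1 - precision ** n_sites``; the accessibility filter exists to
shrink that exposure for the greedy site-selection rules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cssm import CandidateSite, CSSMConfig, select_candidate_sites
from .encode import encode_pair
from .errors import ValidationError
from .network import SiteClassifier, SiteOutput, predict_site
from .seqio import GeneUTR, MatureMiRNA
from .thermo import FoldingBackend, delta_g_open

#: Default site-accessibility threshold, kcal/mol.
TH_SA_DEFAULT = -10.0
DG_OPEN_CONTEXT = 200


@dataclass(frozen=True)
class ScoredSite:
    site: CandidateSite
    output: SiteOutput
    dg_open: float | None = None


@dataclass(frozen=True)
class GenePrediction:
    """Aggregated verdict for one miRNA:gene pair."""

    mirna_id: str
    gene_id: str
    sites: tuple[ScoredSite, ...]
    T: bool
    #: max site score (o1 - o0) over retained sites; -1 when none remain
    gene_score: float
    n_candidates: int  # before filtering
    n_filtered: int    # removed by the accessibility filter


def fp_probability(precision: float, n_sites: int) -> float:
    """Probability of at least one false-positive site call by chance.

    ``1 - precision ** n_sites``: each of ``n_sites`` independently wrong
    with probability (1 - precision) flips the gene-level disjunction.
    """
    if not (0.0 <= precision <= 1.0):
        raise ValidationError("precision must lie in [0, 1]")
    if n_sites < 0:
        raise ValidationError("n_sites must be >= 0")
    return 1.0 - precision ** n_sites


def apply_accessibility_filter(
    sites: list[CandidateSite],
    utr: GeneUTR,
    backend: FoldingBackend,
    th_sa: float = TH_SA_DEFAULT,
    context: int = DG_OPEN_CONTEXT,
    dg_open_values: list[float] | None = None,
) -> tuple[list[CandidateSite], list[float]]:
    """Keep only sites whose opening energy lies at or below the threshold.

    A site is retained iff dG_open <= ``th_sa`` (strictly greater values
    are removed).  Order is preserved; the returned retained set is always
    a subset of the input, so filtering can only remove positives from the
    downstream disjunction, never create them.  Precomputed values can be
    supplied via ``dg_open_values`` (parallel to ``sites``); otherwise each
    site's dG_open is computed over ``context`` nt of UTR around it.
    Returns (retained sites, their dG_open values).
    """
    if dg_open_values is None:
        dg_open_values = [
            delta_g_open(utr, s.window_start, len(s.site_seq), backend, context).dg_open
            for s in sites
        ]
    if len(dg_open_values) != len(sites):
        raise ValidationError("dg_open_values must parallel sites")
    retained, energies = [], []
    for site, dg in zip(sites, dg_open_values):
        if dg <= th_sa:
            retained.append(site)
            energies.append(dg)
    return retained, energies


def predict_gene(
    mirna: MatureMiRNA,
    utr: GeneUTR,
    cssm: CSSMConfig | str,
    model: SiteClassifier,
    backend: FoldingBackend,
    K: float = 0.0,
    accessibility_filter: bool = False,
    th_sa: float = TH_SA_DEFAULT,
    context: int = DG_OPEN_CONTEXT,
) -> GenePrediction:
    """Run the full pipeline for one miRNA:gene pair.

    Steps: candidate-site selection -> optional accessibility filter ->
    per-site network classification -> disjunction.  An empty (or fully
    filtered) candidate set yields T = False and gene_score = -1.
    """
    candidates = select_candidate_sites(mirna, utr, cssm, backend)
    n_candidates = len(candidates)
    dg_values: list[float | None]
    if accessibility_filter:
        retained, energies = apply_accessibility_filter(
            candidates, utr, backend, th_sa=th_sa, context=context
        )
        dg_values = list(energies)
    else:
        retained = candidates
        dg_values = [None] * len(retained)

    scored: list[ScoredSite] = []
    for site, dg in zip(retained, dg_values):
        enc = encode_pair(mirna, site.site_seq, site.up_flank, site.down_flank)
        out = predict_site(model, enc, K=K)
        scored.append(ScoredSite(site=site, output=out, dg_open=dg))

    T = any(s.output.cls == 1 for s in scored)
    gene_score = max((s.output.score for s in scored), default=-1.0)
    return GenePrediction(
        mirna_id=mirna.id,
        gene_id=utr.gene_id,
        sites=tuple(scored),
        T=T,
        gene_score=gene_score,
        n_candidates=n_candidates,
        n_filtered=n_candidates - len(retained),
    )
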