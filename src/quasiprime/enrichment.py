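"""Per-species annotation enrichment and cross-species random-effects combination.

Each species contributes a 2x2 contingency table per annotation term (study
proteins with/without the term vs. the rest of the background). The odds
ratio and its log (LOR) use the Haldane–Anscombe correction (+0.5 on every
cell) so zero cells stay finite; the p-value is a two-sided Fisher exact test
on the raw integer cells. Per-term results across species of the same taxon
are combined with a DerSimonian–Laird random-effects model (Cochran's Q, τ²,
inverse-variance weights) and the combined effects are BH-adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ContingencyTable", "EnrichmentResult", "MetaResult",
           "haldane_anscombe", "fisher_p", "species_enrichment",
           "combine_random_effects", "bh_adjust"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a/b = study proteins with/without term, c/d = background-only."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    """One species' enrichment of one term: OR, LOR, SE(LOR) and Fisher p."""

    species_id: str
    term_id: str
    odds_ratio: float
    lor: float
    se_lor: float
    p_value: float


@dataclass(frozen=True)
class MetaResult:
    """Random-effects combination of one term's per-species LORs."""

    term_id: str
    n_species: int
    cochran_q: float
    tau_squared: float
    combined_lor: float
    se_combined: float
    z: float
    p_value: float
    p_adjusted: float = math.nan


def haldane_anscombe(t: ContingencyTable) -> tuple[float, float, float]:
    """Corrected odds ratio, LOR and SE(LOR): +0.5 added to every cell."""
    a, b, c, d = t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5
    odds_ratio = (a * d) / (b * c)
    lor = math.log(odds_ratio)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return odds_ratio, lor, se


def fisher_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p on the raw integer cells.

    Sum of hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's (a tiny relative
    tolerance absorbs floating-point ties).
    """
    n = t.a + t.b + t.c + t.d
    r1 = t.a + t.b          # study size
    c1 = t.a + t.c          # proteins with term
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0  # a zero margin admits a single table
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[support == t.a][0]
    mask = pmf <= p_obs * (1 + 1e-13)
    if mask.all():
        return 1.0
    return float(min(1.0, pmf[mask].sum()))


def species_enrichment(
    study: set[str],
    background: set[str],
    annotations: Mapping[str, set[str]],
    mode: str = "go",
    species_id: str = "",
    min_study_size: int = 10,
) -> list[EnrichmentResult]:
    """Enrichment of every term observed in the study set, for one species.

    The background is all proteins of the species; term counts are direct
    annotations only (no propagation up any ontology graph). In ``go`` mode
    species whose study set has ``min_study_size`` or fewer proteins are
    skipped (empty result). In ``entries`` mode results are pre-filtered to
    p < 0.05 and OR > 1 before combination.
    """
    if mode not in ("go", "entries"):
        raise ValueError(f"unknown mode {mode!r}")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    if mode == "go" and len(study) <= min_study_size:
        return []
    n_study = len(study)
    n_rest = len(background) - n_study
    terms_in_study: dict[str, int] = {}
    for protein in study:
        for term in annotations.get(protein, ()):
            terms_in_study[term] = terms_in_study.get(term, 0) + 1
    rest = background - study
    results = []
    for term in sorted(terms_in_study):
        a = terms_in_study[term]
        c = sum(1 for protein in rest if term in annotations.get(protein, ()))
        table = ContingencyTable(a=a, b=n_study - a, c=c, d=n_rest - c)
        odds_ratio, lor, se = haldane_anscombe(table)
        p = fisher_p(table)
        if mode == "entries" and not (p < 0.05 and odds_ratio > 1.0):
            continue
        results.append(EnrichmentResult(
            species_id=species_id, term_id=term, odds_ratio=odds_ratio,
            lor=lor, se_lor=se, p_value=p))
    return results


def combine_random_effects(results: Sequence[EnrichmentResult]) -> MetaResult:
    """DerSimonian–Laird random-effects combination of one term's LORs.

    Fixed weights w_i = 1/SE_i²; Cochran's Q and τ² = max(0, (Q − df)/C) with
    C = Σw − Σw²/Σw; adjusted weights 1/(SE_i² + τ²). The combined effect is
    tested with z = LOR̂/SE against a t-distribution with n − 1 degrees of
    freedom (floored at 1 for a single study, which passes through unchanged).
    """
    if not results:
        raise ValueError("no per-species results to combine")
    term_ids = {r.term_id for r in results}
    if len(term_ids) != 1:
        raise ValueError(f"results mix terms: {sorted(term_ids)}")
    lors = np.array([r.lor for r in results])
    ses = np.array([r.se_lor for r in results])
    n = len(results)
    if n == 1:
        q = tau2 = 0.0
        combined, se = float(lors[0]), float(ses[0])
    else:
        w = 1.0 / ses**2
        theta_fixed = float((w * lors).sum() / w.sum())
        q = float((w * (lors - theta_fixed) ** 2).sum())
        c = float(w.sum() - (w**2).sum() / w.sum())
        tau2 = max(0.0, (q - (n - 1)) / c)
        w_star = 1.0 / (ses**2 + tau2)
        combined = float((w_star * lors).sum() / w_star.sum())
        se = float(1.0 / math.sqrt(w_star.sum()))
    z = combined / se
    df = max(n - 1, 1)
    p = float(2.0 * stats.t.sf(abs(z), df))
    return MetaResult(
        term_id=term_ids.pop(), n_species=n, cochran_q=q, tau_squared=tau2,
        combined_lor=combined, se_combined=se, z=z, p_value=min(1.0, p))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def combine_by_term(
    results: Iterable[EnrichmentResult],
    adjust: bool = True,
) -> list[MetaResult]:
    """Group per-species results by term, combine each, and BH-adjust together.

    This is one multiple-testing family: call it separately per (rank, mode,
    term-class) analysis.
    """
    by_term: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_term.setdefault(r.term_id, []).append(r)
    metas = [combine_random_effects(rs) for _, rs in sorted(by_term.items())]
    if adjust and metas:
        adj = bh_adjust([m.p_value for m in metas])
        metas = [MetaResult(**{**m.__dict__, "p_adjusted": a})
                 for m, a in zip(metas, adj)]
    return metas
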