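"""Relationship-hypothesis testing for a trio of individuals.

Each of the three dyads (A-B, A-C, B-C) gets an observed forced-homozygote
Rxy and three class-specific empirical distributions simulated on that
dyad's own shared-SNP panel (the panels differ, so the distributions are
dyad-specific: 3 classes x 3 dyads = nine simulated data sets). A
hypothesis assigns a named relationship to every dyad; its log-likelihood
is the sum over dyads of the log normal density of the observed coefficient
under the class the relationship maps to. Posteriors are the flat-prior
softmax of the log-likelihoods, computed with log-sum-exp stabilisation.

The default hypothesis set is the eleven combinations of full
sibling/parental and half sibling/avuncular relationships that are
genealogically coherent for a trio where B and C may be siblings and A an
outside relative. Named relationships sharing a class (Parent vs Full
Sibling; Uncle vs Half Sibling) are likelihood-equivalent per dyad but kept
as distinct hypotheses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import KinforceError
from .relatedness import RelatednessClass

__all__ = [
    "DYAD_KEYS",
    "Relationship",
    "Hypothesis",
    "TrioReport",
    "fit_normal",
    "default_hypotheses",
    "trio_lnl",
    "posteriors",
    "odds_ratio",
    "evaluate_trio",
]

DYAD_KEYS = ("ab", "ac", "bc")
SIGMA_FLOOR = 1e-6

_CLASS_OF = {
    "Unrelated": RelatednessClass.UNRELATED,
    "Parent": RelatednessClass.FIRST_ORDER,
    "Full Sibling": RelatednessClass.FIRST_ORDER,
    "Uncle": RelatednessClass.SECOND_ORDER,
    "Half Sibling": RelatednessClass.SECOND_ORDER,
}


class Relationship:
    """Named dyad relationships and their relatedness classes."""

    UNRELATED = "Unrelated"
    PARENT = "Parent"
    UNCLE = "Uncle"
    FULL_SIBLING = "Full Sibling"
    HALF_SIBLING = "Half Sibling"

    @staticmethod
    def relatedness_class(name: str) -> RelatednessClass:
        try:
            return _CLASS_OF[name]
        except KeyError as exc:
            raise KinforceError(f"unknown relationship {name!r}") from exc


@dataclass(frozen=True)
class Hypothesis:
    """One relationship assignment for the trio's three dyads."""

    id: int
    rel_ab: str
    rel_ac: str
    rel_bc: str

    @property
    def relationships(self) -> dict[str, str]:
        return {"ab": self.rel_ab, "ac": self.rel_ac, "bc": self.rel_bc}

    @property
    def class_map(self) -> dict[str, RelatednessClass]:
        return {
            k: Relationship.relatedness_class(v) for k, v in self.relationships.items()
        }


def default_hypotheses() -> list[Hypothesis]:
    """The eleven-hypothesis set for (A-B, A-C, B-C)."""
    U, P, UN, FS, HS = (
        Relationship.UNRELATED,
        Relationship.PARENT,
        Relationship.UNCLE,
        Relationship.FULL_SIBLING,
        Relationship.HALF_SIBLING,
    )
    rows = [
        (1, U, U, U),
        (2, U, U, FS),
        (3, U, U, HS),
        (4, UN, UN, FS),
        (5, P, P, FS),
        (6, P, UN, HS),
        (7, UN, P, HS),
        (8, P, U, U),
        (9, UN, U, U),
        (10, U, P, U),
        (11, U, UN, U),
    ]
    return [Hypothesis(i, ab, ac, bc) for i, ab, ac, bc in rows]


def fit_normal(
    samples: Sequence[float] | np.ndarray | "object",
    sigma_floor: float = SIGMA_FLOOR,
) -> tuple[float, float]:
    """Maximum-likelihood normal fit (mean, SD with divisor n).

    Accepts a raw sample array or anything with a ``samples`` attribute
    (an EmpiricalDistribution). The SD is clamped below by ``sigma_floor``
    so degenerate samples still yield a usable density.
    """
    arr = np.asarray(getattr(samples, "samples", samples), dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise KinforceError("fit_normal needs at least 2 samples")
    mu = float(arr.mean())
    sigma = float(np.sqrt(np.mean((arr - mu) ** 2)))  # ML divisor n
    return mu, max(sigma, sigma_floor)


def trio_lnl(
    h: Hypothesis,
    observed: Mapping[str, float],
    dists: Mapping[tuple[str, RelatednessClass], tuple[float, float]],
) -> float:
    """Summed log normal density of the observed Rxy under one hypothesis.

    ``dists`` maps (dyad key, class) to the fitted (mu, sigma) of that
    dyad's simulated distribution. Densities can exceed 1, so the LnL may
    be positive.
    """
    total = 0.0
    for key, cls in h.class_map.items():
        if (key, cls) not in dists:
            raise KinforceError(f"no fitted distribution for dyad {key!r} class {cls.label}")
        mu, sigma = dists[(key, cls)]
        total += float(norm.logpdf(observed[key], loc=mu, scale=sigma))
    return total


def posteriors(
    lnls: Sequence[float],
    prior: Sequence[float] | None = None,
) -> np.ndarray:
    """Normalized posterior probabilities from log-likelihoods.

    posterior_i = prior_i exp(LnL_i) / sum_j prior_j exp(LnL_j), evaluated
    through a log-sum-exp shift so that arbitrarily large or small LnLs are
    safe. The default prior is flat.
    """
    lnl = np.asarray(lnls, dtype=float)
    if lnl.size == 0:
        raise KinforceError("need at least one hypothesis")
    if not np.all(np.isfinite(lnl)):
        raise KinforceError("non-finite log-likelihood")
    if prior is None:
        w = np.ones_like(lnl)
    else:
        w = np.asarray(prior, dtype=float)
        if w.shape != lnl.shape or np.any(w < 0) or w.sum() == 0:
            raise KinforceError("prior must be nonnegative, same length, not all zero")
    shifted = np.where(w > 0, lnl - lnl[w > 0].max(), -np.inf)
    unnorm = w * np.exp(shifted)
    return unnorm / unnorm.sum()


def odds_ratio(
    post: Mapping[int, float],
    subset_a: Sequence[int],
    subset_b: Sequence[int],
) -> tuple[float, bool]:
    """Odds of hypothesis set A versus set B: sum_A posterior / sum_B posterior.

    Returns (ratio, b_is_zero); when set B carries zero posterior the ratio
    is +inf and the flag is set.
    """
    sa, sb = set(subset_a), set(subset_b)
    if not sa or not sb:
        raise KinforceError("both subsets must be nonempty")
    if sa & sb:
        raise KinforceError("subsets must be disjoint")
    num = sum(post[i] for i in sa)
    den = sum(post[i] for i in sb)
    if den == 0.0:
        return math.inf, True
    return num / den, False


@dataclass
class TrioReport:
    """Per-hypothesis LnL and posterior for one trio, plus the inputs used."""

    sample_ids: tuple[str, str, str]
    observed: dict[str, float]
    n_loci: dict[str, int]
    fits: dict[str, dict[str, tuple[float, float]]]  # dyad -> class label -> (mu, sigma)
    hypotheses: list[Hypothesis]
    lnls: list[float]
    posterior: list[float]

    @property
    def top_hypothesis(self) -> Hypothesis:
        return self.hypotheses[int(np.argmax(self.posterior))]

    def posterior_of(self, hypothesis_id: int) -> float:
        for h, p in zip(self.hypotheses, self.posterior):
            if h.id == hypothesis_id:
                return p
        raise KinforceError(f"no hypothesis with id {hypothesis_id}")

    def to_dict(self) -> dict:
        top = self.top_hypothesis
        return {
            "sample_ids": list(self.sample_ids),
            "observed_rxy": self.observed,
            "n_shared_loci": self.n_loci,
            "fits": {
                dyad: {cls: {"mu": mu, "sigma": sigma} for cls, (mu, sigma) in by_cls.items()}
                for dyad, by_cls in self.fits.items()
            },
            "hypotheses": [
                {
                    "id": h.id,
                    "ab": h.rel_ab,
                    "ac": h.rel_ac,
                    "bc": h.rel_bc,
                    "lnl": lnl,
                    "posterior": p,
                }
                for h, lnl, p in zip(self.hypotheses, self.lnls, self.posterior)
            ],
            "top_hypothesis": {"id": top.id, "ab": top.rel_ab, "ac": top.rel_ac, "bc": top.rel_bc},
            "odds_top_vs_rest": odds_ratio(
                {h.id: p for h, p in zip(self.hypotheses, self.posterior)},
                [top.id],
                [h.id for h in self.hypotheses if h.id != top.id],
            )[0],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def format_table(self) -> str:
        a, b, c = self.sample_ids
        lines = [
            f"{'#':>2}  {a+'-'+b:<14}{a+'-'+c:<14}{b+'-'+c:<14}{'Model LnL':>12}  Posterior"
        ]
        for h, lnl, p in zip(self.hypotheses, self.lnls, self.posterior):
            lines.append(
                f"{h.id:>2}  {h.rel_ab:<14}{h.rel_ac:<14}{h.rel_bc:<14}{lnl:>12.4f}  {p:.4e}"
            )
        return "\n".join(lines)


def evaluate_trio(
    sample_ids: tuple[str, str, str],
    observed: Mapping[str, float],
    fits: Mapping[tuple[str, RelatednessClass], tuple[float, float]],
    n_loci: Mapping[str, int] | None = None,
    hypotheses: Sequence[Hypothesis] | None = None,
    prior: Sequence[float] | None = None,
) -> TrioReport:
    """Score every hypothesis and assemble the report."""
    hyps = list(hypotheses) if hypotheses is not None else default_hypotheses()
    lnls = [trio_lnl(h, observed, fits) for h in hyps]
    post = posteriors(lnls, prior)
    by_dyad: dict[str, dict[str, tuple[float, float]]] = {}
    for (dyad, cls), ms in fits.items():
        by_dyad.setdefault(dyad, {})[cls.label] = ms
    return TrioReport(
        sample_ids=tuple(sample_ids),  # type: ignore[arg-type]
        observed=dict(observed),
        n_loci=dict(n_loci) if n_loci else {k: 0 for k in DYAD_KEYS},
        fits=by_dyad,
        hypotheses=hyps,
        lnls=[float(x) for x in lnls],
        posterior=[float(x) for x in post],
    )
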