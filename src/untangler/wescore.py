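"""The weighted-energy (wE) model-quality score.

For each validation category the score combines two weighted summaries of
the sigma-deviates d_i (energies E_i = d_i²):

* the mean energy ⟨E⟩, weighted by the χ² cumulative probability of Σd²
  with n degrees of freedom — near 1 when the observed deviate distribution
  is far broader than the restraint sigmas predict, near 0 when it is far
  tighter, and exactly 0.5 when Σd² sits at the χ² median;
* the worst energy max(E), clipped by a logarithmic plateau above 10 and
  weighted by softPnn — the probability that the maximum of n independent
  standard-normal magnitudes stays below the observed worst deviate, i.e.
  the probability that the worst outlier is not noise.

The scalar score is

    wE = Σ_category [ w_χ²·⟨E⟩ + w_softPnn·clip(max E) ] + ⟨E_LJ⟩

where ⟨E_LJ⟩, the mean normalized Lennard-Jones energy over all non-bond
pairs, enters unweighted and unclipped and is the only term that can be
negative (it reaches −1 when every pair rests at its optimal separation).
Because clipping saturates each category's worst term near 10, a model with
severe outliers in k categories typically scores on the order of 10·k.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .model import EnsembleModel
from .restraints import CATEGORIES, RestraintSet

CLIP_KNEE = 10.0


def clip_energy(e):
    """Plateau for large statistical energies: identity up to 10, then
    10 + ln(1 + (E − 10)).

    Monotone and continuous with slope ≤ 1 beyond the knee, so reducing a
    moderate outlier (6σ → 3σ) outweighs slightly worsening an extreme one
    (20σ → 20.4σ).
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("statistical energy must be non-negative")
    out = np.where(e > CLIP_KNEE, CLIP_KNEE + np.log1p(
        np.maximum(e - CLIP_KNEE, 0.0)), e)
    return float(out) if out.ndim == 0 else out


def soft_pnn(worst_deviate: float, n: int) -> float:
    """Weight on a category's worst outlier: the probability that the
    maximum of n standard-normal magnitudes is below the observed worst
    deviate, (2Φ(d) − 1)ⁿ.

    ≈ 0 for a 1σ worst deviate in a category of 100 (pure noise), ≈ 1 for a
    6σ worst deviate (not noise).
    """
    if worst_deviate < 0:
        raise ValueError("deviate magnitude must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    p_one = special.erf(worst_deviate / math.sqrt(2.0))
    return float(p_one ** n)


def chi2_weight(deviates) -> float:
    """Weight on a category's mean energy: χ²_n CDF at Σd²."""
    d = np.asarray(deviates, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one deviate")
    return float(stats.chi2.cdf(np.sum(d * d), df=d.size))


def prob_to_sigma_deviate(p: float) -> float:
    """Equivalent normal deviate whose two-sided tail probability is p.

    Used to put probability-based scores (rotamer, Ramachandran) on the
    same sigma scale as geometric deviates.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("probability must be in (0, 1]")
    return float(stats.norm.isf(p / 2.0))


@dataclass
class CategoryReport:
    category: str
    n: int
    deviates: np.ndarray
    mean_energy: float = 0.0
    worst_energy: float = 0.0
    clipped_worst: float = 0.0
    w_avg: float = 0.0
    w_worst: float = 0.0
    contribution: float = 0.0

    def as_dict(self) -> dict:
        return {"category": self.category, "n": self.n,
                "mean_energy": self.mean_energy,
                "worst_energy": self.worst_energy,
                "clipped_worst": self.clipped_worst,
                "w_avg": self.w_avg, "w_worst": self.w_worst,
                "contribution": self.contribution}


@dataclass
class WEScore:
    reports: dict[str, CategoryReport] = field(default_factory=dict)
    mean_lj: float = 0.0
    wE: float = 0.0

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps({
            "wE": self.wE,
            "mean_lj": self.mean_lj,
            "categories": {c: r.as_dict() for c, r in self.reports.items()},
        }, indent=indent)


def category_report(category: str, deviates: np.ndarray) -> CategoryReport:
    deviates = np.asarray(deviates, dtype=float)
    rep = CategoryReport(category=category, n=int(deviates.size),
                         deviates=deviates)
    if deviates.size == 0:
        return rep  # empty category contributes exactly 0
    energies = deviates * deviates
    rep.mean_energy = float(energies.mean())
    rep.worst_energy = float(energies.max())
    rep.clipped_worst = float(clip_energy(rep.worst_energy))
    rep.w_avg = chi2_weight(deviates)
    rep.w_worst = soft_pnn(float(deviates.max()), rep.n)
    rep.contribution = rep.w_avg * rep.mean_energy \
        + rep.w_worst * rep.clipped_worst
    return rep


def we_score(model: EnsembleModel, rset: RestraintSet,
             x: np.ndarray | None = None) -> WEScore:
    """Aggregate all category deviates of a model into the scalar wE."""
    if x is None:
        x = model.coords()
    dev_by_cat = rset.category_deviate_arrays(x)
    score = WEScore()
    total = 0.0
    for cat in CATEGORIES:
        if cat == "nonbond":
            continue
        rep = category_report(cat, dev_by_cat.get(cat, np.zeros(0)))
        score.reports[cat] = rep
        total += rep.contribution
    score.mean_lj = rset.mean_lj(x)
    score.wE = total + score.mean_lj
    return score
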