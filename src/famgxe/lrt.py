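"""Likelihood-ratio tests with boundary-corrected mixture-chi-square nulls.

When a tested parameter lies on the boundary of its space under the null
(a variance, or the decay rate lambda >= 0), the LRT statistic is not
asymptotically chi-square but a weighted mixture of chi-squares, possibly
including a point mass at zero (a "chi-square with 0 df").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

#: largest tolerated negative log-likelihood difference before the LRT
#: statistic is treated as an optimizer failure rather than roundoff
_NEG_TOL = 1e-6


@dataclass(frozen=True)
class MixtureChiSq:
    """Mixture of chi-square distributions; df = 0 denotes a point mass at 0."""

    components: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for w, df in self.components:
            if w <= 0:
                raise ValueError("mixture weights must be positive")
            if int(df) != df or df < 0:
                raise ValueError("df must be a non-negative integer")
            total += w
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixture weights sum to {total}, expected 1")

    def sf(self, t: float) -> float:
        return mixture_sf(t, self)

    def __str__(self) -> str:
        return " + ".join(f"{w:g}*chi2_{df}" for w, df in self.components)


@dataclass
class LRTResult:
    """One likelihood-ratio contrast: statistic, null distribution, p-value."""

    contrast: str
    T: float
    null: MixtureChiSq
    p: float
    loglik_full: float
    loglik_reduced: float


def lrt_statistic(loglik_full: float, loglik_reduced: float) -> float:
    """T = 2*(loglik_full - loglik_reduced), clamped at zero.

    A reduced model beating the full one by more than numerical roundoff
    indicates the full-model optimizer failed and is raised as an error.
    """
    diff = loglik_full - loglik_reduced
    if diff < -_NEG_TOL:
        raise RuntimeError(
            "full-model log-likelihood below reduced-model log-likelihood "
            f"({loglik_full} < {loglik_reduced}): optimizer failure"
        )
    return max(2.0 * diff, 0.0)


def mixture_sf(T: float, null: MixtureChiSq) -> float:
    """Survival function of a mixture-chi-square at T >= 0.

    The point-mass (df = 0) component contributes its full weight at T = 0
    and nothing for T > 0, so T = 0 maps to p = 1 under any valid mixture.
    """
    if T < 0:
        raise ValueError("LRT statistic must be non-negative")
    p = 0.0
    for w, df in null.components:
        if df == 0:
            p += w if T <= 0 else 0.0
        else:
            p += w * float(stats.chi2.sf(T, df))
    return min(p, 1.0)


def standard_contrasts() -> dict[str, MixtureChiSq]:
    """Null distributions for the standard model contrasts.

    - variance_homogeneity (gamma_g = 0): interior parameter, plain chi2_1;
    - genetic_correlation_one (lambda = 0): boundary, 1/2 chi2_0 + 1/2 chi2_1;
    - full_vs_polygenic (gamma_g = gamma_e = lambda = 0): three parameters,
      one on the boundary, 1/2 chi2_2 + 1/2 chi2_3;
    - h2_zero (sigma2_g = 0): boundary, 1/2 chi2_0 + 1/2 chi2_1.
    """
    return {
        "variance_homogeneity": MixtureChiSq(components=((1.0, 1),)),
        "genetic_correlation_one": MixtureChiSq(components=((0.5, 0), (0.5, 1))),
        "full_vs_polygenic": MixtureChiSq(components=((0.5, 2), (0.5, 3))),
        "h2_zero": MixtureChiSq(components=((0.5, 0), (0.5, 1))),
    }


def get_contrast(name: str) -> MixtureChiSq:
    contrasts = standard_contrasts()
    if name not in contrasts:
        raise KeyError(
            f"unknown contrast {name!r}; known: {sorted(contrasts)}"
        )
    return contrasts[name]
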