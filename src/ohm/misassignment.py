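"""Homolog misassignment: estimation, contamination, mixture inversion, null.

A haplotype-resolved Hi-C library misassigns a read pair's homolog with some
probability ``p_hm`` (per pair; per side ``p_hm/2``), turning cis pairs into
apparent trans-homolog pairs and vice versa.  Because dangling ends make
inward cis pairs at short separations vastly more abundant than any true
trans-homolog signal, the ratio of inward trans-homolog to inward cis contact
frequency at 300-600 bp is an upper estimate of ``p_hm``.  The observed
curves are a two-component mixture,

    obs_homolog(s) = (1 - p) * true_homolog(s) + p * true_cis(s)
    obs_cis(s)     = (1 - p) * true_cis(s)     + p * true_homolog(s)

which can be inverted bin by bin, and a no-pairing null for the observed
trans-homolog curve is the cross-parent trans-heterolog level plus
``p * P_cis(s)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedEstimateError
from .scaling import ScalingCurve


@dataclass
class HMEstimate:
    """An upper estimate of the probability of homolog misassignment.

    ``p_hm`` is per paired read (the per-side probability is ``p_hm/2``);
    ``s_range`` is the separation window of the geometric mean and
    ``stringency`` the ``(min_snv, max_mismatch)`` filter under which the
    curves were computed.  ``ratios`` holds the per-bin frequency ratios that
    entered the mean (geometric mean over binned curve ratios, each bin
    weighted equally).
    """

    p_hm: float
    s_range: tuple[float, float]
    stringency: tuple[int, float] | None
    ratios: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self):
        if not 0 <= self.p_hm <= 1:
            raise InvalidParameterError("p_hm must be in [0, 1]")


@dataclass
class NoPairingNull:
    """Expected observed trans-homolog frequency under zero pairing."""

    edges: np.ndarray
    expected: np.ndarray
    heterolog_freq: float
    p_hm: float

    def compare(
        self,
        observed: ScalingCurve,
        min_expected: float = 10.0,
        excess_factor: float = 10.0,
    ) -> pd.DataFrame:
        """Per-bin comparison of an observed trans-homolog curve to the null.

        Expected counts are ``expected * possible``; z-scores use the Poisson
        standard deviation and are reported only where the expectation reaches
        ``min_expected`` (the normal approximation breaks down below).
        ``exceeds`` flags bins where the observed frequency is more than
        ``excess_factor`` times the null.
        """
        if len(observed.edges) != len(self.edges) or not np.allclose(
            observed.edges, self.edges
        ):
            raise InvalidParameterError("observed curve is on a different grid")
        exp_counts = self.expected * observed.possible
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (observed.observed - exp_counts) / np.sqrt(exp_counts)
            ratio = observed.frequency / self.expected
        z = np.where(exp_counts >= min_expected, z, np.nan)
        return pd.DataFrame(
            {
                "s_lo": self.edges[:-1],
                "s_hi": self.edges[1:],
                "observed": observed.observed,
                "expected": exp_counts,
                "z": z,
                "obs_over_null": ratio,
                "exceeds": ratio > excess_factor,
            }
        )


def estimate_phm(
    cis_inward: ScalingCurve,
    homolog_inward: ScalingCurve,
    s_range: tuple[float, float] = (300.0, 600.0),
    stringency: tuple[int, float] | None = None,
    zero_pseudocount: float = 0.5,
) -> HMEstimate:
    """Estimate p_hm from the dangling-end signature (upper bound).

    Geometric mean, over the separation bins intersecting ``s_range``, of the
    inward trans-homolog to inward cis frequency ratio.  Bins where the
    trans-homolog curve observed zero pairs contribute a pseudo-count of
    ``zero_pseudocount`` pairs instead of minus infinity.  A zero cis
    frequency in the range is an error (the signature is absent).
    """
    if not cis_inward.same_grid(homolog_inward):
        raise InvalidParameterError("curves must share a separation grid")
    lo, hi = s_range
    if hi > 1000.0 or lo <= 0 or lo >= hi:
        raise InvalidParameterError(
            "s_range must lie within the dangling-end regime (0, 1000] bp"
        )
    edges = cis_inward.edges
    in_range = (edges[1:] > lo) & (edges[:-1] < hi)
    if not in_range.any():
        raise InvalidParameterError("no separation bins intersect s_range")
    cis_f = cis_inward.frequency[in_range]
    hom_obs = homolog_inward.observed[in_range]
    hom_possible = homolog_inward.possible[in_range]
    if np.any(~np.isfinite(cis_f)) or np.any(cis_f <= 0):
        raise UndefinedEstimateError(
            "cis inward frequency vanishes within s_range; no dangling-end signature"
        )
    hom_f = np.where(hom_obs > 0, hom_obs, zero_pseudocount) / hom_possible
    ratios = hom_f / cis_f
    p_hm = float(np.exp(np.mean(np.log(ratios))))
    return HMEstimate(
        p_hm=min(p_hm, 1.0),
        s_range=(lo, hi),
        stringency=stringency,
        ratios=ratios,
        bin_edges=edges[:-1][in_range],
    )


def contamination_fraction(
    p_hm: float, cis_ps: ScalingCurve, homolog_obs: ScalingCurve
) -> np.ndarray:
    """Fraction of observed trans-homolog contacts that are misassigned cis.

    ``p_hm * P_cis(s) / P_homolog_obs(s)`` per bin, clamped to [0, 1]; NaN
    where the observed trans-homolog frequency is zero or undefined.
    """
    if not cis_ps.same_grid(homolog_obs):
        raise InvalidParameterError("curves must share a separation grid")
    hom = homolog_obs.frequency
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = p_hm * cis_ps.frequency / hom
    frac = np.where(np.isfinite(hom) & (hom > 0), frac, np.nan)
    return np.clip(frac, 0.0, 1.0)


def correct_ps(
    homolog_obs: ScalingCurve, cis_obs: ScalingCurve, p_hm: float
) -> tuple[ScalingCurve, ScalingCurve]:
    """Invert the misassignment mixture, returning (homolog_true, cis_true).

    Solves the symmetric 2x2 mixture per bin; exact inverse of the forward
    mixture for any ``p_hm != 0.5`` (at 0.5 the mixture is singular).
    """
    if p_hm >= 1:
        raise InvalidParameterError("p_hm must be < 1")
    if abs(1.0 - 2.0 * p_hm) < 1e-12:
        raise InvalidParameterError("mixture is singular at p_hm = 0.5")
    det = 1.0 - 2.0 * p_hm
    hom = homolog_obs.frequency
    cis = cis_obs.frequency
    true_hom = ((1.0 - p_hm) * hom - p_hm * cis) / det
    true_cis = ((1.0 - p_hm) * cis - p_hm * hom) / det
    out = []
    for freq, template, label in (
        (true_hom, homolog_obs, "trans_homolog_true"),
        (true_cis, cis_obs, "cis_true"),
    ):
        out.append(
            ScalingCurve(
                edges=template.edges,
                observed=np.where(np.isfinite(freq), freq, 0.0) * template.possible,
                possible=template.possible,
                labels={**template.labels, "corrected": True, "pair_class": label},
            )
        )
    return out[0], out[1]


def no_pairing_null(
    heterolog_freq: float, cis_ps: ScalingCurve, p_hm: float
) -> NoPairingNull:
    """Expected trans-homolog P(s) in the absence of pairing.

    Cross-parent trans-heterolog level plus ``p_hm`` times the cis curve;
    flat at the heterolog baseline when ``p_hm = 0`` and never below it.
    """
    cis = np.nan_to_num(cis_ps.frequency, nan=0.0)
    return NoPairingNull(
        edges=cis_ps.edges,
        expected=heterolog_freq + p_hm * cis,
        heterolog_freq=heterolog_freq,
        p_hm=p_hm,
    )
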