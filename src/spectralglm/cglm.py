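"""Complex general linear model: HTF estimation and hypothesis testing.

The measured BOLD series are modelled, voxel by voxel, as the convolution of
known binary stimulus trains with unknown run-specific impulse responses
plus stationary zero-mean noise.  In the Fourier domain this becomes, at
each frequency, an ordinary linear model with complex coefficients: the
hemodynamic transfer function (HTF) matrix ``A(lambda)`` (R stimuli x S
runs).  Band-averaged cross-spectra give a stable estimate

    A_hat = f_rr^{-1} f_rs                                  (R x S)

and a null hypothesis ``B A C^T = 0`` — with B (b x R) combining stimuli
and C (c x S) combining runs — is tested with the complex Wilks-type
statistic

    U = det(G_c) / det(G_c + H)

where G_c = C G C^T is the residual ("error") spectral matrix under the
contrast and H the hypothesis matrix.  Rao's approximation turns U into an
F statistic with degrees of freedom (2bc, 2h); the factors of 2 account for
the real and imaginary parts of the cross-spectral estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral import (
    ConfigurationError,
    MultiRunSeries,
    SpectraBundle,
    StimulusSet,
    cross_spectra_from_data,
)

__all__ = [
    "Contrast",
    "TransferEstimate",
    "HypothesisMatrices",
    "TestResult",
    "ContrastResult",
    "estimate_htf",
    "error_spectral_matrix",
    "hypothesis_matrices",
    "wilks_u",
    "rao_f",
    "pvalue",
    "standard_contrasts",
    "omnibus_contrast",
    "simple_effect_contrast",
    "pairwise_run_contrast",
    "run_voxelwise_tests",
]

_HERMITIAN_IMAG_TOL = 1e-9


class DegenerateDesignError(ValueError):
    """Stimulus auto-spectrum (or a contrast of it) is numerically singular."""


class SingularResidualError(ValueError):
    """Residual spectral matrix singular: too few in-band frequencies."""


# ---------------------------------------------------------------------------
# contrasts


@dataclass(frozen=True)
class Contrast:
    """A null hypothesis ``B a(lambda) C^T = 0``.

    ``B`` (b x R, full row rank) combines stimulus inputs; ``C`` (c x S,
    full row rank) combines repeated runs.  ``univariate`` marks tests that
    reduce to a single scalar transfer function (b = c = 1 with one-hot or
    sign rows); the hierarchical masking procedure gates these less
    stringently than the multivariate tests.
    """

    B: np.ndarray
    C: np.ndarray
    name: str
    univariate: bool = False

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        if np.linalg.matrix_rank(B) != B.shape[0]:
            raise ConfigurationError(f"contrast {self.name!r}: B is not full row rank")
        if np.linalg.matrix_rank(C) != C.shape[0]:
            raise ConfigurationError(f"contrast {self.name!r}: C is not full row rank")

    @property
    def b(self) -> int:
        return self.B.shape[0]

    @property
    def c(self) -> int:
        return self.C.shape[0]

    def check_dims(self, R: int, S: int) -> None:
        if self.B.shape[1] != R or self.C.shape[1] != S:
            raise ConfigurationError(
                f"contrast {self.name!r} has B {self.B.shape}, C {self.C.shape}; "
                f"design has R={R}, S={S}"
            )


def omnibus_contrast(R: int, S: int) -> Contrast:
    """Identity B and C: do any stimuli evoke a response in any run?"""
    return Contrast(np.eye(R), np.eye(S), "omnibus")


def simple_effect_contrast(stimulus: int, run: int, R: int, S: int) -> Contrast:
    """One-hot rows selecting a single (stimulus, run) cell."""
    B = np.zeros((1, R))
    B[0, stimulus] = 1.0
    C = np.zeros((1, S))
    C[0, run] = 1.0
    return Contrast(B, C, f"simple-s{stimulus}-r{run}", univariate=True)


def pairwise_run_contrast(run_a: int, run_b: int, R: int, S: int) -> Contrast:
    """Sum over stimuli, difference between two runs."""
    B = np.ones((1, R))
    C = np.zeros((1, S))
    C[0, run_a], C[0, run_b] = 1.0, -1.0
    return Contrast(B, C, f"runs-{run_a}-vs-{run_b}", univariate=True)


def _interaction_C(S: int) -> np.ndarray:
    """Successive-difference rows [1 -1 0; 0 1 -1; ...], (S-1) x S."""
    C = np.zeros((S - 1, S))
    for i in range(S - 1):
        C[i, i], C[i, i + 1] = 1.0, -1.0
    return C


def standard_contrasts(R: int, S: int) -> dict[str, Contrast]:
    """Named library of hypothesis tests.

    For the demonstration design of two stimulus valences (pos, neg) and
    three task states (cog, emo, pas) — (R, S) = (2, 3) — this returns the
    full compilation of 22 named tests: the omnibus test (listed once per
    subject group in the demonstration design), the stimulus-by-state
    interaction, the multivariate state and stimulus effects, and the
    univariate simple effects (a few of which recur under a second name
    because they are conventionally reported at two slice levels).

    For other (R, S) the generic members — omnibus, interaction,
    state/stimulus main effects, pairwise run differences and single-cell
    simple effects — are generated from the same building blocks.
    """
    ones_R = np.ones((1, R))
    lib: dict[str, Contrast] = {"omnibus": omnibus_contrast(R, S)}
    if R >= 2 and S >= 2:
        lib["interaction"] = Contrast(
            np.array([[1.0, -1.0]]) if R == 2 else _interaction_C(R),
            _interaction_C(S),
            "interaction",
        )
        lib["state-effect"] = Contrast(ones_R, _interaction_C(S), "state-effect")
        lib["stimulus-effect"] = Contrast(
            np.array([[1.0, -1.0]]) if R == 2 else _interaction_C(R),
            np.ones((1, S)),
            "stimulus-effect",
        )
    if (R, S) != (2, 3):
        for a in range(S):
            for b in range(a + 1, S):
                ct = pairwise_run_contrast(a, b, R, S)
                lib[ct.name] = ct
        for i in range(R):
            for j in range(S):
                ct = simple_effect_contrast(i, j, R, S)
                lib[ct.name] = ct
        return lib

    # Demonstration-design compilation.  Stimulus order (pos, neg); state
    # order (cog, emo, pas).
    pos, neg = np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])
    diff, both = np.array([[1.0, -1.0]]), np.array([[1.0, 1.0]])
    cog, emo, pas = (
        np.array([[1.0, 0.0, 0.0]]),
        np.array([[0.0, 1.0, 0.0]]),
        np.array([[0.0, 0.0, 1.0]]),
    )
    cog_emo = np.array([[1.0, -1.0, 0.0]])
    emo_pas = np.array([[0.0, 1.0, -1.0]])
    cog_pas = np.array([[1.0, 0.0, -1.0]])

    def add(name: str, B, C, univariate: bool = False) -> None:
        lib[name] = Contrast(B, C, name, univariate=univariate)

    # the compilation lists the omnibus test twice (once per subject); the
    # generic "omnibus" entry covers the first, this alias the second
    add("omnibus-alcoholic", np.eye(2), np.eye(3))
    add("state-effect-cog-vs-emo", both, cog_emo)
    add("state-effect-emo-vs-pas", both, emo_pas)
    add("state-effect-cog-vs-pas", both, cog_pas)
    add("neg-emo-vs-pas", neg, emo_pas, univariate=True)
    add("neg-cog-vs-pas", neg, cog_pas, univariate=True)
    add("neg-cog-vs-emo", neg, cog_emo, univariate=True)
    add("neg-pas", neg, pas, univariate=True)
    add("neg-cog", neg, cog, univariate=True)
    add("neg-emo", neg, emo, univariate=True)
    add("pos-emo", pos, emo, univariate=True)
    add("stimulus-effect-emo", diff, emo, univariate=True)
    add("state-effect-cog", both, cog, univariate=True)
    add("state-effect-emo", both, emo, univariate=True)
    add("state-effect-pas", both, pas, univariate=True)
    add("neg-emo-language", neg, emo, univariate=True)
    add("pos-emo-language", pos, emo, univariate=True)
    add("stimulus-effect-emo-language", diff, emo, univariate=True)
    return lib


# ---------------------------------------------------------------------------
# estimation


@dataclass(frozen=True)
class TransferEstimate:
    """Band-wise nonparametric HTF estimate.

    ``A_hat[j, v]`` is the R x S complex matrix of band ``j`` at voxel
    ``v``; entry (i, k) is the transfer function linking stimulus ``i`` to
    run ``k``.
    """

    A_hat: np.ndarray  # (n_bands, V, R, S)
    partition: "object"
    stim_labels: tuple[str, ...] = ()
    run_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class HypothesisMatrices:
    """Ingredients of one contrast's test, per band and voxel."""

    E: np.ndarray  # (n_bands, V, b, c)
    V: np.ndarray  # (n_bands, b, b) — voxel independent
    H: np.ndarray  # (n_bands, V, c, c)
    G: np.ndarray  # (n_bands, V, S, S)
    G_c: np.ndarray  # (n_bands, V, c, c)


@dataclass(frozen=True)
class TestResult:
    """One contrast's statistics at a single (band, voxel)."""

    U: float
    F: float
    d: float
    h: float
    df: tuple[int, float]
    p: float
    band_center: float
    voxel: int


def _check_conditioning(mats: np.ndarray, cond_max: float, what: str) -> None:
    conds = np.linalg.cond(mats)
    bad = np.flatnonzero(~(conds < cond_max))
    if bad.size:
        raise DegenerateDesignError(
            f"degenerate stimulus design: {what} ill-conditioned in band(s) "
            f"{bad.tolist()} (condition number >= {cond_max:g})"
        )


def estimate_htf(bundle: SpectraBundle, cond_max: float = 1e8) -> TransferEstimate:
    """HTF estimate ``A_hat = f_rr^{-1} f_rs`` per band and voxel.

    This equals the complex least-squares solution obtained by stacking the
    2m+1 in-band frequencies of the stimulus and BOLD transforms and solving
    the normal equations, i.e. the unweighted minimum-mean-square-error
    estimate.
    """
    _check_conditioning(bundle.f_rr, cond_max, "f_rr")
    # solve broadcasts (n_bands, 1, R, R) against (n_bands, V, R, S)
    A = np.linalg.solve(bundle.f_rr[:, np.newaxis], bundle.f_rs)
    return TransferEstimate(
        A_hat=A,
        partition=bundle.partition,
        stim_labels=bundle.stim_labels,
        run_labels=bundle.run_labels,
    )


def _hermitize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + np.conj(np.swapaxes(M, -1, -2)))


def error_spectral_matrix(bundle: SpectraBundle, cond_max: float = 1e8) -> np.ndarray:
    """Residual spectral matrix ``G = (2m+1)(f_ss - f_sr f_rr^{-1} f_rs)``.

    ``f_sr`` is the Hermitian transpose of ``f_rs``.  The result is
    symmetrized as ``(G + G^H)/2`` to suppress floating-point asymmetry;
    it is Hermitian PSD up to rounding.
    """
    _check_conditioning(bundle.f_rr, cond_max, "f_rr")
    A = np.linalg.solve(bundle.f_rr[:, np.newaxis], bundle.f_rs)
    f_sr = np.conj(np.swapaxes(bundle.f_rs, -1, -2))
    G = bundle.partition.width * (bundle.f_ss - f_sr @ A)
    return _hermitize(G)


def hypothesis_matrices(
    estimate: TransferEstimate,
    bundle: SpectraBundle,
    contrast: Contrast,
    cond_max: float = 1e8,
) -> HypothesisMatrices:
    """E, V, H, G and G_c for one contrast.

    E = B A_hat C^T (b x c); V = B f_rr^{-1} B^T (b x b, voxel independent);
    H = (2m+1) E^H V^{-1} E (c x c); G_c = C G C^T (c x c).
    """
    contrast.check_dims(bundle.R, bundle.S)
    B, C = contrast.B, contrast.C
    E = B @ estimate.A_hat @ C.T
    V = B @ np.linalg.solve(bundle.f_rr, np.broadcast_to(
        B.T, (bundle.f_rr.shape[0],) + B.T.shape).copy())
    conds = np.linalg.cond(V)
    bad = np.flatnonzero(~(conds < cond_max))
    if bad.size:
        raise DegenerateDesignError(
            f"contrast {contrast.name!r} not estimable in band(s) {bad.tolist()}: "
            "V singular"
        )
    EH = np.conj(np.swapaxes(E, -1, -2))
    H = bundle.partition.width * (EH @ np.linalg.solve(V[:, np.newaxis], E))
    G = error_spectral_matrix(bundle, cond_max=cond_max)
    G_c = C @ G @ C.T
    return HypothesisMatrices(E=E, V=V, H=_hermitize(H), G=G, G_c=_hermitize(G_c))


# ---------------------------------------------------------------------------
# test statistics


def _real_det(M: np.ndarray) -> np.ndarray:
    """Determinant of (batched) Hermitian matrices, asserted real."""
    det = np.linalg.det(np.asarray(M, dtype=complex))
    scale = np.maximum(np.abs(det), 1.0)
    if np.any(np.abs(det.imag) > _HERMITIAN_IMAG_TOL * scale):
        raise FloatingPointError(
            "determinant of a Hermitian matrix has a non-negligible imaginary part"
        )
    return det.real


def wilks_u(G_c: np.ndarray, H: np.ndarray) -> float:
    """Wilks-type statistic ``U = det(G_c) / det(G_c + H)`` in (0, 1].

    Requires G_c Hermitian positive definite and H Hermitian PSD; a
    singular G_c means the band holds too few frequencies for the model
    size (2m+1 must exceed R + c - b).
    """
    G_c = np.atleast_2d(np.asarray(G_c, dtype=complex))
    H = np.atleast_2d(np.asarray(H, dtype=complex))
    det_g = _real_det(G_c)
    det_gh = _real_det(G_c + H)
    if not det_g > 0 or not np.isfinite(det_g):
        raise SingularResidualError(
            "residual spectral matrix singular: need 2m+1 > R + c - b "
            "in-band frequencies and nondegenerate data"
        )
    return float(det_g / det_gh)


def rao_f(
    U: float | np.ndarray, b: int, c: int, m: int, R: int
) -> tuple[np.ndarray | float, int, float, float, float]:
    """Rao's F approximation of the complex Wilks statistic.

    Returns ``(F, df1, df2, d, h)`` with ``df1 = 2bc``, ``df2 = 2h`` and

        d = sqrt((b^2 c^2 - 4) / (b^2 + c^2 - 5))   if b^2 + c^2 != 5
            1                                        if b^2 + c^2 == 5
        h = [2m + 1 - R - (c - b + 1)/2] d - bc/2 + 1
        F = (h / bc) (U^{-1/d} - 1)

    The doubled degrees of freedom account for the cross-spectral estimates
    having both real and imaginary parts.
    """
    if b < 1 or c < 1 or m < 1 or R < 1:
        raise ConfigurationError("b, c, m, R must all be positive")
    if b * b + c * c == 5:
        d = 1.0
    else:
        d = float(np.sqrt((b * b * c * c - 4.0) / (b * b + c * c - 5.0)))
    h = (2 * m + 1 - R - (c - b + 1) / 2.0) * d - b * c / 2.0 + 1.0
    if h <= 0:
        raise ConfigurationError(
            f"band too narrow for this contrast: h = {h} <= 0 "
            f"(b={b}, c={c}, m={m}, R={R})"
        )
    U_arr = np.asarray(U, dtype=float)
    if np.any((U_arr <= 0) | (U_arr > 1)):
        raise ValueError("U must lie in (0, 1]")
    F = (h / (b * c)) * (U_arr ** (-1.0 / d) - 1.0)
    if np.ndim(U) == 0:
        F = float(F)
    return F, 2 * b * c, 2.0 * h, d, h


def pvalue(F: float | np.ndarray, df1: float, df2: float) -> float | np.ndarray:
    """Upper-tail probability of the central F distribution."""
    if df1 <= 0 or df2 <= 0:
        raise ConfigurationError("degrees of freedom must be positive")
    p = stats.f.sf(F, df1, df2)
    return float(p) if np.ndim(F) == 0 else p


# ---------------------------------------------------------------------------
# voxelwise driver


@dataclass(frozen=True)
class ContrastResult:
    """Per-band, per-voxel maps of one contrast's statistics.

    ``U``, ``F`` and ``p`` have shape (n_bands, V).  ``degenerate`` flags
    voxels whose residual spectral matrix was singular in at least one band
    (for example all-zero data); their statistics are NaN, never a silent
    p-value.
    """

    contrast: Contrast
    U: np.ndarray
    F: np.ndarray
    p: np.ndarray
    d: float
    h: float
    df: tuple[int, float]
    degenerate: np.ndarray  # (V,) bool
    partition: "object"

    def at(self, band: int, voxel: int) -> TestResult:
        return TestResult(
            U=float(self.U[band, voxel]),
            F=float(self.F[band, voxel]),
            d=self.d,
            h=self.h,
            df=self.df,
            p=float(self.p[band, voxel]),
            band_center=float(self.partition.center_frequencies[band]),
            voxel=voxel,
        )


def _estimability_guard(contrast: Contrast, m: int, R: int) -> None:
    # residual df must stay positive: 2m+1 >= R + c + 1
    if 2 * m + 1 < R + contrast.c + 1:
        raise ConfigurationError(
            f"contrast {contrast.name!r}: band width {2 * m + 1} too small "
            f"for R={R}, c={contrast.c} (need 2m+1 >= R + c + 1)"
        )


def evaluate_contrast(
    estimate: TransferEstimate,
    bundle: SpectraBundle,
    contrast: Contrast,
    cond_max: float = 1e8,
) -> ContrastResult:
    """Evaluate one contrast over every band and voxel."""
    m = bundle.partition.m
    _estimability_guard(contrast, m, bundle.R)
    mats = hypothesis_matrices(estimate, bundle, contrast, cond_max=cond_max)
    det_g = _real_det(mats.G_c)
    det_gh = _real_det(mats.G_c + mats.H)
    with np.errstate(divide="ignore", invalid="ignore"):
        U = det_g / det_gh
    ok = (det_g > 0) & np.isfinite(U) & (U > 0)
    U = np.where(ok, np.clip(U, None, 1.0), np.nan)
    F_valid, df1, df2, d, h = rao_f(np.where(ok, U, 0.5), contrast.b, contrast.c, m, bundle.R)
    F = np.where(ok, F_valid, np.nan)
    p = np.where(ok, stats.f.sf(np.where(ok, F, 1.0), df1, df2), np.nan)
    degenerate = ~ok.all(axis=0)
    if degenerate.any():
        warnings.warn(
            f"contrast {contrast.name!r}: {int(degenerate.sum())} voxel(s) with "
            "singular residual spectral matrix flagged as degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return ContrastResult(
        contrast=contrast,
        U=U,
        F=F,
        p=p,
        d=d,
        h=h,
        df=(df1, df2),
        degenerate=degenerate,
        partition=bundle.partition,
    )


def run_voxelwise_tests(
    series: MultiRunSeries,
    stimuli: StimulusSet,
    contrasts: list[Contrast] | dict[str, Contrast],
    m: int,
    cond_max: float = 1e8,
) -> dict[str, ContrastResult]:
    """Full chain dft -> cross-spectra -> A_hat -> U -> F -> p, per contrast.

    The stimulus auto-spectrum ``f_rr`` and every contrast's ``V`` matrix
    are computed once per band (they carry no spatial dependency); results
    are independent of voxel evaluation order.
    """
    if isinstance(contrasts, dict):
        contrasts = list(contrasts.values())
    bundle = cross_spectra_from_data(stimuli, series, m)
    estimate = estimate_htf(bundle, cond_max=cond_max)
    out: dict[str, ContrastResult] = {}
    for contrast in contrasts:
        out[contrast.name] = evaluate_contrast(estimate, bundle, contrast, cond_max=cond_max)
    return out
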