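"""Synthetic two-group cohorts of band-limited ROI time series.

The generator emulates the statistical structure a functional-connectivity
pipeline assumes: each subject's 90-ROI signal is a sum of latent
band-limited Gaussian components (white noise filtered into the slow-5,
slow-4 and a high out-of-analysis band), each mixed through the Cholesky
factor of a group correlation matrix, plus white observation noise.  The
two groups share a common sparse positive-definite base correlation
template; group B differs from group A by ``delta_correlation`` on the
configured ``effect_edges``, and the difference is carried exclusively by
the component(s) of ``effect_band``.  Band-specific empirical Pearson
correlations therefore recover the injected deltas, which is exactly the
quantity the downstream pipeline measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bands import DEFAULT_BANDS, FrequencyBand, bandpass_array

__all__ = [
    "CohortSpec",
    "RoiTimeSeries",
    "generate_cohort",
    "ground_truth_features",
    "group_correlations",
    "module_effect_edges",
    "EFFECT_MODULE_ROIS",
]

#: Feature-block order inside one band's nodal-feature table.
METRIC_ORDER = ("ND", "BC", "NL")

#: ROIs of the reference validation effect: a fully connected module whose
#: within-module connectivity is elevated in group B.  A multi-ROI module is
#: what a detectable group difference looks like at cohort-level estimation
#: noise (a 130-sample slow-5 correlation has an SD near 0.28, so isolated
#: single-edge effects are statistically invisible).
EFFECT_MODULE_ROIS = (5, 7, 9, 11, 13, 15)


def module_effect_edges(
    rois: tuple[int, ...] = EFFECT_MODULE_ROIS, delta: float = 0.50
) -> tuple[tuple[int, int, float], ...]:
    """All within-module edges elevated by ``delta`` (the validation effect)."""
    return tuple((i, j, delta) for k, i in enumerate(rois) for j in rois[k + 1:])
#: Band order used when per-band tables are concatenated ("all band").
BAND_ORDER = ("full", "slow4", "slow5")


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's ROI × time signal matrix with its group label."""

    subject_id: str
    group: str  # "A" or "B"
    data: np.ndarray  # n_rois × n_timepoints
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (n_rois x n_timepoints) matrix")
        if not np.all(np.isfinite(data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in data")
        n_rois, n_t = data.shape
        if n_t < 2 * n_rois:
            warnings.warn(
                f"subject {self.subject_id}: {n_t} timepoints < 2 x {n_rois} ROIs; "
                "correlation estimates will be noisy",
                stacklevel=2,
            )

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic two-group cohort.

    ``effect_edges`` are 1-based ROI pairs ``(i, j, delta)`` with i < j;
    group B's correlation on those pairs differs from group A's by delta,
    carried by the ``effect_band`` latent component.
    """

    n_group_a: int
    n_group_b: int
    n_rois: int = 90
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    seed: int = 0
    effect_edges: tuple[tuple[int, int, float], ...] = ()
    effect_band: str = "slow5"
    noise_sd: float = 0.5
    base_density: float = 0.10
    base_strength: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_edges", tuple(tuple(e) for e in self.effect_edges))
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.effect_band not in ("full", "slow4", "slow5"):
            raise ValueError(f"effect_band must be one of full/slow4/slow5, got {self.effect_band!r}")
        for i, j, _delta in self.effect_edges:
            if not (1 <= i < j <= self.n_rois):
                raise ValueError(f"effect edge ({i},{j}) violates 1 <= i < j <= n_rois={self.n_rois}")

    @property
    def effect_rois(self) -> set[int]:
        return {r for i, j, _ in self.effect_edges for r in (i, j)}


# ---------------------------------------------------------------------------
# correlation structure


def _template_offdiag(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Random sparse symmetric off-diagonal template shared by both groups.

    Effect pairs are left template-silent so the injected delta IS the group
    difference, not delta plus whatever the template happened to draw there.
    """
    n = spec.n_rois
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    mask = rng.random(n_pairs) < spec.base_density
    mags = rng.uniform(0.6 * spec.base_strength, 1.4 * spec.base_strength, size=n_pairs)
    signs = rng.choice([-1.0, 1.0], size=n_pairs)
    vals = np.where(mask, mags * signs, 0.0)
    w = np.zeros((n, n))
    w[iu] = vals
    w = w + w.T
    for i, j, _ in spec.effect_edges:
        w[i - 1, j - 1] = 0.0
        w[j - 1, i - 1] = 0.0
    return w


def group_correlations(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Target correlation matrices (group A, group B) for the effect band.

    The shared template is shrunk toward identity until both groups' targets
    are positive definite with margin, so feasibility depends only on the
    requested effect edges; an infeasible effect (non-PD even on an identity
    template, or |r| >= 1) raises ``ValueError`` naming the offending edges.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_rois
    delta_m = np.zeros((n, n))
    for i, j, delta in spec.effect_edges:
        delta_m[i - 1, j - 1] += delta
        delta_m[j - 1, i - 1] += delta
    bad = [(i, j) for i, j, _ in spec.effect_edges if abs(delta_m[i - 1, j - 1]) >= 1.0]
    if bad:
        raise ValueError(f"effect edges push correlations outside (-1, 1): {bad}")
    if np.linalg.eigvalsh(np.eye(n) + delta_m)[0] <= 1e-6:
        raise ValueError(
            "group B target covariance is not positive definite; "
            f"offending effect edges: {[(i, j) for i, j, _ in spec.effect_edges]}"
        )
    w = _template_offdiag(spec, rng)
    for _ in range(60):
        base = np.eye(n) + w
        cb = base + delta_m
        if np.linalg.eigvalsh(base)[0] > 0.05 and np.linalg.eigvalsh(cb)[0] > 0.01:
            return base, cb
        w *= 0.9
    return np.eye(n), np.eye(n) + delta_m


def _component_bands(spec: CohortSpec) -> dict[str, FrequencyBand]:
    """Latent components: the two analysis sub-bands plus an out-of-band
    high-frequency component (no group structure) when the TR allows one."""
    comps = {"slow5": DEFAULT_BANDS["slow5"], "slow4": DEFAULT_BANDS["slow4"]}
    nyquist = 1.0 / (2.0 * spec.tr_seconds)
    lo, hi = 1.05 * DEFAULT_BANDS["slow4"].f_high, 0.95 * nyquist
    if lo < hi:
        comps["high"] = FrequencyBand("high", lo, hi)
    return comps


def _effect_components(effect_band: str) -> tuple[str, ...]:
    # a "full"-band effect lives in both analysis sub-bands
    return ("slow4", "slow5") if effect_band == "full" else (effect_band,)


# ---------------------------------------------------------------------------
# generation


def _band_limited_unit_noise(
    rng: np.random.Generator, n_rois: int, n_t: int, tr: float, band: FrequencyBand
) -> np.ndarray:
    """Independent band-limited rows standardized to unit sample variance."""
    white = rng.standard_normal((n_rois, n_t))
    x = bandpass_array(white, tr, band)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_cohort(spec: CohortSpec) -> list[RoiTimeSeries]:
    """Draw the full cohort (group A then group B), deterministically.

    Each subject is the sum over latent components of ``L_g @ U`` where the
    rows of ``U`` are independent unit-variance band-limited noise and
    ``L_g L_g^T`` is the group's target correlation for that component,
    plus ``noise_sd`` white noise.
    """
    rng = np.random.default_rng(spec.seed)
    base, effected = group_correlations(spec, rng)
    comps = _component_bands(spec)
    effect_in = set(_effect_components(spec.effect_band))
    chol: dict[tuple[str, str], np.ndarray] = {}
    for name in comps:
        cb = effected if name in effect_in else base
        chol[(name, "A")] = np.linalg.cholesky(base)
        chol[(name, "B")] = np.linalg.cholesky(cb)
    # flat-spectrum power allocation: each component carries variance
    # proportional to its bandwidth, as filtered white noise does; the total
    # signal variance is normalized to 1
    bw = {name: band.f_high - band.f_low for name, band in comps.items()}
    total_bw = sum(bw.values())
    amp = {name: np.sqrt(b / total_bw) for name, b in bw.items()}

    subjects: list[RoiTimeSeries] = []
    groups = ["A"] * spec.n_group_a + ["B"] * spec.n_group_b
    for idx, group in enumerate(groups):
        x = np.zeros((spec.n_rois, spec.n_timepoints))
        for name, band in comps.items():
            u = _band_limited_unit_noise(rng, spec.n_rois, spec.n_timepoints, spec.tr_seconds, band)
            x += amp[name] * (chol[(name, group)] @ u)
        if spec.noise_sd > 0:
            x += spec.noise_sd * rng.standard_normal(x.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short-series warning is per-spec, not per-subject
            subjects.append(
                RoiTimeSeries(subject_id=f"sub-{idx + 1:04d}", group=group, data=x, tr_seconds=spec.tr_seconds)
            )
    if spec.n_timepoints < 2 * spec.n_rois:
        warnings.warn(
            f"n_timepoints={spec.n_timepoints} < 2 x n_rois={spec.n_rois}; "
            "correlation estimates will be noisy",
            stacklevel=2,
        )
    return subjects


def ground_truth_features(
    spec: CohortSpec,
    layout: str = "band",
    n_rois: int | None = None,
) -> set[int]:
    """Indices of nodal features whose ROIs participate in the effect edges.

    With ``layout='band'`` the indices address the effect band's own
    270-column table (block order ND, BC, NL; ROI-major inside a block).
    With ``layout='all'`` they address the concatenated three-band table
    (band blocks in ``BAND_ORDER``).
    """
    n = spec.n_rois if n_rois is None else n_rois
    per_band = len(METRIC_ORDER) * n
    if layout == "band":
        offset = 0
    elif layout == "all":
        offset = BAND_ORDER.index(spec.effect_band) * per_band
    else:
        raise ValueError(f"layout must be 'band' or 'all', got {layout!r}")
    out: set[int] = set()
    for roi in spec.effect_rois:
        for m_idx in range(len(METRIC_ORDER)):
            out.add(offset + m_idx * n + (roi - 1))
    return out
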