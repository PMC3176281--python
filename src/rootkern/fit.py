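"""Maximum-likelihood inverse fitting of root-distribution models.

The observation model treats each sequenced root fragment as an independent
draw from the expected species composition at its core's location, so a
core with counts ``n_1..n_S`` over taxa contributes a multinomial
log-likelihood ``sum_s n_s log p_s`` where ``p_s`` comes from the forward
model (:func:`rootkern.forward.expected_proportions`).  Maximizing over
``beta`` and the kernel's distance parameters, separately per kernel family
and scale mode, and comparing by AIC reproduces the classic inverse-modeling
workflow for dispersal kernels, transplanted below ground: sources are
mapped stems, samples are soil cores, and genotype categories are species.

An alternative least-squares objective on observed mass proportions is
provided for data with reliable per-fragment masses.

Numerical strategy: parameters are transformed to an unconstrained scale
(logistic-bounded ``beta`` and ``theta``, log-bounded distance scale and
tail exponent), then each family is optimized by Nelder-Mead simplex from
``n_starts`` seeded random starts; the best local optimum wins.  Everything
is deterministic given the configuration seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.special import expit, logit

from .datamodel import CoreDataset, SoilCore, StemMap, filter_by_depth
from .errors import ConfigurationError, EdgeEffectError, UndefinedValueError
from .forward import RootModelParams
from .kernels import (DEFAULT_R_MAX, FAMILY_ORDER, KernelFamily,
                      KernelParams, THRESHOLD_FAMILIES, kernel_pdf)

log = logging.getLogger(__name__)

SCALE_MODES = ("constant", "diameter_power")
OBJECTIVES = ("multinomial_counts", "mass_proportion_ls")

#: Search bounds on the natural scale.  beta spans the plausible range of
#: mass-diameter exponents (pipe-model ~2, coarse-root studies up to ~2.6);
#: alpha covers sub-meter to plot-scale kernels; theta in [0, 2] allows the
#: distance scale to grow up to quadratically with diameter; the
#: inverse-power tail p must exceed 2 for integrability.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "beta": (0.0, 4.0),
    "alpha": (0.25, 100.0),
    "theta": (0.0, 2.0),
    "power": (2.05, 10.0),
}

#: Probability floor per unmatched taxon when the background is enabled.
BACKGROUND_FLOOR = 1e-6

_LOG_FLOOR = 1e-300


@dataclass
class FitConfig:
    """Configuration of a fitting run.

    Attributes
    ----------
    families, scale_modes
        Which kernel families and distance-scale modes to try.  The
        hyperbolic family is scale-free, so it is fitted only once
        regardless of scale modes.
    objective
        ``multinomial_counts`` (default) or ``mass_proportion_ls``.
    depth_cutoff
        Fragments deeper than this (cm) are excluded before fitting.
    n_starts, seed
        Multi-start count and RNG seed for start points.
    bounds
        Per-parameter search bounds; see :data:`DEFAULT_BOUNDS`.
    tolerance
        Simplex function-value convergence tolerance.
    background
        Relative background density b (>= 0); enables the background
        category when positive.
    ignore_edge
        Allow cores near the mapped boundary (set when the generating
        process is known to contain no unmapped outside stems).
    r_max_default
        Cutoff radius (m) for the hyperbolic family and the edge margin.
    max_evals
        Function-evaluation cap per start.
    """

    families: Sequence[KernelFamily] = FAMILY_ORDER
    scale_modes: Sequence[str] = ("constant",)
    objective: str = "multinomial_counts"
    depth_cutoff: float = 20.0
    n_starts: int = 8
    seed: int = 20110919
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    tolerance: float = 1e-7
    background: float = 0.0
    ignore_edge: bool = False
    r_max_default: float = DEFAULT_R_MAX
    max_evals: int = 1500

    def __post_init__(self):
        if self.n_starts < 1:
            raise ConfigurationError("n_starts must be >= 1")
        if not self.families:
            raise ConfigurationError("families must be non-empty")
        if self.objective not in OBJECTIVES:
            raise ConfigurationError(f"unknown objective {self.objective!r}")
        for m in self.scale_modes:
            if m not in SCALE_MODES:
                raise ConfigurationError(f"unknown scale mode {m!r}")


@dataclass
class FitResult:
    """Outcome of fitting one (family, scale mode) combination."""

    params: RootModelParams
    scale_mode: str
    log_likelihood: float
    n_params: int
    aic: float
    r_squared: float
    per_species_residuals: dict[str, float]
    converged: bool
    n_function_evals: int
    dataset_key: str = ""
    aicc: float = float("nan")

    @property
    def family(self) -> KernelFamily:
        return self.params.family


# ---------------------------------------------------------------------------
# parameter transforms


def _bounded(u, lo, hi):
    return lo + (hi - lo) * expit(u)


def _inv_bounded(v, lo, hi):
    return float(logit((v - lo) / (hi - lo)))


class _Layout:
    """Maps an unconstrained vector to kernel/model parameters and back."""

    def __init__(self, family: KernelFamily, scale_mode: str,
                 config: FitConfig):
        self.family = KernelFamily(family)
        self.scale_mode = scale_mode
        self.config = config
        names = ["beta"]
        if self.family is not KernelFamily.HYPERBOLIC:
            names.append("alpha")
            if self.family is KernelFamily.INVERSE_POWER:
                names.append("power")
            if scale_mode == "diameter_power":
                names.append("theta")
        self.names = names

    @property
    def n_params(self) -> int:
        return len(self.names)

    def _b(self, name):
        return self.config.bounds.get(name, DEFAULT_BOUNDS[name])

    def to_params(self, u: np.ndarray) -> RootModelParams:
        vals = {}
        for name, ui in zip(self.names, u):
            lo, hi = self._b(name)
            if name in ("alpha", "power"):
                # log-scale interpolation keeps multiplicative geometry
                vals[name] = float(math.exp(
                    _bounded(ui, math.log(lo), math.log(hi))))
            else:
                vals[name] = float(_bounded(ui, lo, hi))
        theta = vals.get("theta", 0.0)
        if self.family is KernelFamily.HYPERBOLIC:
            kp = KernelParams(r_max=self.config.r_max_default)
        elif self.family in THRESHOLD_FAMILIES:
            # alpha plays the cutoff radius (diameter-scaled when theta > 0)
            kp = KernelParams(alpha=vals["alpha"], theta=theta)
        else:
            kp = KernelParams(alpha=vals["alpha"], theta=theta,
                              power=vals.get("power"))
        return RootModelParams(beta=vals["beta"], family=self.family,
                               kernel=kp, background=self.config.background)

    def center(self) -> np.ndarray:
        """Transformed coordinates of a neutral start point."""
        natural = {"beta": 1.5, "alpha": 5.0, "theta": 0.5, "power": 3.0}
        u = []
        for name in self.names:
            lo, hi = self._b(name)
            v = min(max(natural[name], lo * 1.001), hi * 0.999)
            if name in ("alpha", "power"):
                u.append(_inv_bounded(math.log(v), math.log(lo),
                                      math.log(hi)))
            else:
                u.append(_inv_bounded(v, lo, hi))
        return np.array(u)


# ---------------------------------------------------------------------------
# likelihood machinery


def _dataset_key(dataset: CoreDataset) -> str:
    ids = ",".join(sorted(c.core_id for c in dataset.cores))
    return f"{dataset.n_cores}c/{dataset.n_fragments}f/{hash(ids) & 0xFFFFFFFF:08x}"


class _Problem:
    """Precomputed quantities for repeated likelihood evaluation.

    Distances between cores and stems never change during optimization, so
    the (cores x stems) distance matrix, the stem-to-taxon indicator and
    the observed count matrix are built once.
    """

    def __init__(self, dataset: CoreDataset, stem_map: StemMap,
                 config: FitConfig):
        self.config = config
        ds = filter_by_depth(dataset, config.depth_cutoff)
        self.dataset_key = _dataset_key(dataset)
        counts = ds.counts()
        counts = counts.loc[counts.sum(axis=1) > 0]  # cores with data
        if counts.empty:
            raise ConfigurationError("no cores with fragments after "
                                     f"depth cutoff {config.depth_cutoff} cm")
        mapped = set(stem_map.species_codes())
        observed = list(counts.columns)
        self.taxa = [t for t in observed if t in mapped]
        self.unmatched = [t for t in observed if t not in mapped]
        if not self.taxa:
            raise ConfigurationError(
                "no overlap between fragment taxa and the stem map "
                "(enable the background to fit anyway)")
        if self.unmatched and config.background <= 0:
            log.info("dropping %d taxa without mapped stems (%d fragments): %s",
                     len(self.unmatched),
                     int(counts[self.unmatched].to_numpy().sum()),
                     ", ".join(self.unmatched))
        self.core_ids = list(counts.index)
        self.N = counts[self.taxa].to_numpy(dtype=float)
        self.n_unmatched_frags = (
            counts[self.unmatched].to_numpy(dtype=float).sum(axis=1)
            if self.unmatched else np.zeros(len(counts)))
        by_id = {c.core_id: c for c in ds.cores}
        self.points = np.array([[by_id[i].x, by_id[i].y]
                                for i in self.core_ids])
        if not (config.ignore_edge or stem_map.buffer_available):
            x0, y0, x1, y1 = stem_map.bounds
            m = config.r_max_default
            near = [cid for cid, (px, py) in zip(self.core_ids, self.points)
                    if px - x0 < m or x1 - px < m or py - y0 < m or y1 - py < m]
            if near:
                raise EdgeEffectError(
                    f"cores {near} lie within {m:.0f} m of the mapped "
                    "boundary; unmapped outside stems could bias the fit "
                    "(set buffer_available or ignore_edge)")
        a = stem_map.arrays
        self._x = a["x"]
        self._y = a["y"]
        self.z = a["dbh"]
        self.D = np.hypot(self.points[:, 0:1] - self._x[None, :],
                          self.points[:, 1:2] - self._y[None, :])
        codes = a["species"]
        self.A = np.zeros((len(codes), len(self.taxa)))
        for j, t in enumerate(self.taxa):
            self.A[codes == t, j] = 1.0
        self.n_obs = float(self.N.sum() + self.n_unmatched_frags.sum())
        self._mass_P_obs = None

    # -- forward quantities ------------------------------------------------

    def predicted(self, params: RootModelParams):
        """Per-core predicted proportions over the fitted taxa, plus the
        background share (0 when disabled)."""
        pdf = kernel_pdf(params.family, params.kernel, self.D,
                         self.z[None, :])
        C = self.z[None, :] ** params.beta * pdf
        S = C @ self.A
        denom = C.sum(axis=1) + params.background
        with np.errstate(invalid="ignore", divide="ignore"):
            P = S / denom[:, None]
            p_bg = np.where(denom > 0, params.background / denom, 0.0)
        return P, p_bg, denom

    def observed_proportions(self) -> np.ndarray:
        """Per-core observed count proportions over the fitted taxa."""
        tot = self.N.sum(axis=1, keepdims=True)
        return self.N / np.where(tot > 0, tot, 1.0)

    # -- objectives --------------------------------------------------------

    def nll(self, params: RootModelParams) -> float:
        """Multinomial negative log-likelihood in nats (clipped: a taxon
        observed where the model predicts zero yields a large but finite
        penalty so the simplex can recover)."""
        P, p_bg, denom = self.predicted(params)
        if np.any(~np.isfinite(denom)) or np.any(denom <= 0):
            return 1e12
        val = -(self.N * np.log(np.clip(P, _LOG_FLOOR, None))).sum()
        if params.background > 0 and self.n_unmatched_frags.any():
            per_taxon = np.clip(p_bg / max(len(self.unmatched), 1),
                                BACKGROUND_FLOOR, None)
            val -= (self.n_unmatched_frags * np.log(per_taxon)).sum()
        return float(val) if np.isfinite(val) else 1e12

    def ss_objective(self, params: RootModelParams) -> float:
        """Least-squares objective on proportions (counts fall back when
        masses are unavailable; this engine always has counts)."""
        P, _, denom = self.predicted(params)
        if np.any(~np.isfinite(denom)) or np.any(denom <= 0):
            return 1e12
        resid = self.observed_proportions() - P
        return float((resid ** 2).sum())

    def objective(self, params: RootModelParams) -> float:
        if self.config.objective == "mass_proportion_ls":
            return self.ss_objective(params)
        return self.nll(params)

    def r_squared(self, params: RootModelParams) -> float:
        """Fraction of variation in observed proportions explained."""
        P, _, _ = self.predicted(params)
        return proportion_r_squared(self.observed_proportions(), P)

    def residuals(self, params: RootModelParams) -> dict[str, float]:
        obs = self.observed_proportions()
        P, _, _ = self.predicted(params)
        mean_resid = (obs - P).mean(axis=0)
        return {t: float(v) for t, v in zip(self.taxa, mean_resid)}


# ---------------------------------------------------------------------------
# public operations


def proportion_r_squared(observed, predicted) -> float:
    """``1 - SS_res / SS_tot`` over all (core, taxon) proportion pairs.

    ``SS_tot`` is taken about the grand mean of the observed proportions.
    Equals 1 for perfect predictions, 0 when every prediction is the grand
    mean, and may be negative for models worse than the grand mean.  Raises
    :class:`~rootkern.errors.UndefinedValueError` when all observed
    proportions are equal (zero total sum of squares).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ss_res = float(((obs - pred) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        raise UndefinedValueError(
            "all observed proportions equal; variation explained is "
            "undefined")
    return 1.0 - ss_res / ss_tot


def observed_proportions(dataset: CoreDataset, core: SoilCore | str,
                         taxa: Sequence[str],
                         mode: str = "counts") -> np.ndarray:
    """Observed composition of one core over an ordered taxon set.

    ``mode='mass'`` weights fragments by dry mass; if any retained fragment
    lacks a mass the call falls back to counts with a warning.  Fragments
    of taxa outside ``taxa`` are ignored.
    """
    core_id = core if isinstance(core, str) else core.core_id
    frags = [f for f in dataset.fragments_for(core_id)
             if f.taxon_code in set(taxa)]
    if not frags:
        raise ConfigurationError(f"core {core_id!r} has no fragments in the "
                                 "requested taxon set")
    if mode == "mass" and any(f.mass is None for f in frags):
        warnings.warn(f"core {core_id!r}: missing fragment masses; "
                      "falling back to counts")
        mode = "counts"
    w = np.zeros(len(taxa))
    idx = {t: i for i, t in enumerate(taxa)}
    for f in frags:
        w[idx[f.taxon_code]] += f.mass if mode == "mass" else 1.0
    return w / w.sum()


def negative_log_likelihood(dataset: CoreDataset, stem_map: StemMap,
                            params: RootModelParams,
                            config: FitConfig | None = None) -> float:
    """Multinomial negative log-likelihood of the core data (nats).

    Returns ``inf`` when some observed taxon has predicted proportion zero
    and the background is disabled; the offending (core, taxon) pairs are
    reported through a warning.
    """
    config = config or FitConfig()
    prob = _Problem(dataset, stem_map, config)
    P, _, _ = prob.predicted(params)
    zero = (prob.N > 0) & (P <= 0)
    if zero.any() and params.background <= 0:
        pairs = [(prob.core_ids[i], prob.taxa[j])
                 for i, j in zip(*np.nonzero(zero))]
        warnings.warn("observed taxa with zero predicted proportion: "
                      f"{pairs}")
        return math.inf
    return prob.nll(params)


def variation_explained(dataset: CoreDataset, stem_map: StemMap,
                        params: RootModelParams,
                        config: FitConfig | None = None) -> float:
    """1 - SS_res/SS_tot over all (core, taxon) observed-vs-predicted
    proportions in the fitted taxon set; may be negative for bad models."""
    config = config or FitConfig()
    return _Problem(dataset, stem_map, config).r_squared(params)


def fit_family(dataset: CoreDataset, stem_map: StemMap,
               family: KernelFamily, scale_mode: str = "constant",
               config: FitConfig | None = None,
               _problem: "_Problem | None" = None) -> FitResult:
    """Fit one kernel family by seeded multi-start Nelder-Mead.

    Deterministic given the configuration seed.  If no start converges the
    best incumbent is returned with ``converged=False``.
    """
    config = config or FitConfig()
    family = KernelFamily(family)
    if scale_mode not in SCALE_MODES:
        raise ConfigurationError(f"unknown scale mode {scale_mode!r}")
    prob = _problem if _problem is not None else _Problem(
        dataset, stem_map, config)
    layout = _Layout(family, scale_mode, config)
    rng = np.random.default_rng(config.seed)
    center = layout.center()
    starts = [center]
    for _ in range(config.n_starts - 1):
        starts.append(center + rng.normal(0.0, 1.5, size=layout.n_params))

    def f(u):
        return prob.objective(layout.to_params(u))

    best = None
    converged = False
    nfev = 0
    for x0 in starts:
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"maxfev": config.max_evals,
                                "xatol": 1e-4,
                                "fatol": config.tolerance})
        nfev += res.nfev
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = layout.to_params(best.x)
    nll = prob.nll(params)
    k = layout.n_params
    n = prob.n_obs
    try:
        r2 = prob.r_squared(params)
    except UndefinedValueError:
        r2 = float("nan")
    aicc_pen = (2.0 * k * (k + 1) / (n - k - 1)) if n > k + 1 else math.inf
    return FitResult(
        params=params, scale_mode=scale_mode, log_likelihood=-nll,
        n_params=k, aic=2.0 * k + 2.0 * nll, r_squared=r2,
        per_species_residuals=prob.residuals(params),
        converged=converged, n_function_evals=nfev,
        dataset_key=prob.dataset_key,
        aicc=2.0 * k + 2.0 * nll + aicc_pen)


def fit_all(dataset: CoreDataset, stem_map: StemMap,
            config: FitConfig | None = None) -> list[FitResult]:
    """Fit every configured (family, scale mode) combination.

    The scale-free hyperbolic family is fitted once regardless of the
    scale-mode list.
    """
    config = config or FitConfig()
    prob = _Problem(dataset, stem_map, config)
    results = []
    for family in config.families:
        family = KernelFamily(family)
        modes = (("constant",) if family is KernelFamily.HYPERBOLIC
                 else config.scale_modes)
        for mode in modes:
            results.append(fit_family(dataset, stem_map, family, mode,
                                      config, _problem=prob))
    return results


def select_model(results: Sequence[FitResult],
                 criterion: str = "aic") -> FitResult:
    """Pick the minimum-AIC result (or AICc with ``criterion='aicc'``).

    Ties break toward fewer parameters, then family enumeration order.
    All results must come from the same dataset.
    """
    results = list(results)
    if not results:
        raise ConfigurationError("no fit results to select from")
    keys = {r.dataset_key for r in results}
    if len(keys) > 1:
        raise ConfigurationError(
            f"fit results come from different datasets: {sorted(keys)}")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}

    def sort_key(r: FitResult):
        score = r.aicc if criterion == "aicc" else r.aic
        return (score, r.n_params, order[r.params.family])

    return min(results, key=sort_key)


# ---------------------------------------------------------------------------
# serialization


def write_fit_result(result: FitResult, path) -> None:
    """Serialize a fit result as a flat, stably ordered YAML document."""
    k = result.params.kernel
    doc = {
        "family": result.params.family.value,
        "scale_mode": result.scale_mode,
        "beta": float(result.params.beta),
        "alpha": None if k.alpha is None else float(k.alpha),
        "theta": float(k.theta),
        "power": None if k.power is None else float(k.power),
        "r_max": None if k.r_max is None else float(k.r_max),
        "background": float(result.params.background),
        "log_likelihood": float(result.log_likelihood),
        "n_params": int(result.n_params),
        "aic": float(result.aic),
        "aicc": float(result.aicc),
        "r_squared": float(result.r_squared),
        "converged": bool(result.converged),
        "n_function_evals": int(result.n_function_evals),
        "dataset_key": result.dataset_key,
        "per_species_residuals": {
            t: float(v)
            for t, v in sorted(result.per_species_residuals.items())},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_fit_result(path) -> FitResult:
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        kp = KernelParams(alpha=doc["alpha"], theta=doc["theta"],
                          power=doc["power"], r_max=doc["r_max"])
        params = RootModelParams(beta=doc["beta"],
                                 family=KernelFamily(doc["family"]),
                                 kernel=kp, background=doc["background"])
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"malformed fit result {path}: {exc}") from exc
    return FitResult(
        params=params, scale_mode=doc["scale_mode"],
        log_likelihood=doc["log_likelihood"], n_params=doc["n_params"],
        aic=doc["aic"], r_squared=doc["r_squared"],
        per_species_residuals=dict(doc.get("per_species_residuals", {})),
        converged=doc["converged"],
        n_function_evals=doc["n_function_evals"],
        dataset_key=doc.get("dataset_key", ""),
        aicc=doc.get("aicc", float("nan")))
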