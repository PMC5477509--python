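"""SFS-based comparison of four split/bottleneck/migration demographic models.

Model ids: ``BN+MIG``, ``BN``, ``NOBN+MIG``, ``NOBN``. Parameters are scaled
by the ancestral size: nu_b = N_b/N_a, nu_w = N_w/N_a, tau_b = T_b/(2 N_a),
tau = T/(2 N_a), M = 2 N_a m. Expected spectra are Monte-Carlo estimates
from the rescaled forward engine (no diffusion solver); model comparison
uses a multinomial composite log-likelihood over the folded, projected,
singleton-masked joint SFS, which is theta-free and valid for relative
ranking. Within one optimization run the same site-simulation seeds are
reused for every parameter evaluation (common random numbers), making the
likelihood surface deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import InputError, ParameterError
from .sim import mutate_freqs
from .stats import (
    SFS,
    build_sfs,
    fold_sfs,
    folded_support,
    mask_singletons,
    project_sfs,
)

MODEL_IDS = ("BN+MIG", "BN", "NOBN+MIG", "NOBN")

PARAM_NAMES = {
    "BN+MIG": ("nu_b", "nu_w", "tau_b", "tau", "M"),
    "BN": ("nu_b", "nu_w", "tau_b", "tau"),
    "NOBN+MIG": ("nu_w", "tau", "M"),
    "NOBN": ("nu_w", "tau"),
}

#: models able to represent (nest) the keyed generating model
NESTING_MODELS = {
    "BN+MIG": {"BN+MIG"},
    "BN": {"BN", "BN+MIG"},
    "NOBN+MIG": {"NOBN+MIG", "BN+MIG"},
    "NOBN": {"NOBN", "NOBN+MIG", "BN", "BN+MIG"},
}

DEFAULT_BOUNDS = {
    "nu_b": (0.01, 0.9),
    "nu_w": (0.02, 4.0),
    "tau_b": (0.005, 0.15),
    "tau": (0.01, 0.4),
    "M": (0.02, 8.0),
}

#: scenario presets used for model-recovery experiments (scaled parameters);
#: chosen so each scenario's folded joint SFS is poorly mimicked by the
#: model families that do not nest it
MODEL_PRESETS = {
    "BN": {"nu_b": 0.02, "nu_w": 2.0, "tau_b": 0.08, "tau": 0.15},
    "BN+MIG": {"nu_b": 0.02, "nu_w": 2.0, "tau_b": 0.08, "tau": 0.15, "M": 2.0},
    "NOBN": {"nu_w": 0.25, "tau": 0.35},
    "NOBN+MIG": {"nu_w": 0.25, "tau": 0.35, "M": 2.0},
}


@dataclass
class DemographicModel:
    model_id: str
    params: dict

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ParameterError(f"unknown model id {self.model_id!r}")
        names = PARAM_NAMES[self.model_id]
        if set(self.params) != set(names):
            raise ParameterError(
                f"{self.model_id} needs parameters {names}, got {tuple(self.params)}"
            )
        for k in ("nu_b", "nu_w"):
            if k in self.params and self.params[k] <= 0:
                raise ParameterError(f"{k} must be > 0")
        for k in ("tau_b", "tau", "M"):
            if k in self.params and self.params[k] < 0:
                raise ParameterError(f"{k} must be >= 0")

    @property
    def has_bottleneck(self) -> bool:
        return self.model_id.startswith("BN")

    @property
    def has_migration(self) -> bool:
        return self.model_id.endswith("+MIG")


@dataclass
class FitResult:
    model_id: str
    best_params: dict
    max_ll: float
    runs: pd.DataFrame  # one row per run: start/best params, LL
    median_params: dict = field(default_factory=dict)


def ne_from_theta(theta, mu, L=1.0) -> int:
    """Ancestral effective size from theta = 4 Ne mu L, truncated to int."""
    if theta <= 0 or mu <= 0 or L <= 0:
        raise ParameterError("theta, mu and L must all be > 0")
    return int(math.floor(theta / (4.0 * mu * L)))


# ---------------------------------------------------------------------------
# Monte-Carlo expected SFS
# ---------------------------------------------------------------------------

_POOL_CACHE: dict = {}
_POOL_CACHE_MAX = 8


def _seed_key(seed):
    return tuple(seed) if isinstance(seed, (list, tuple)) else (int(seed),)


def _ancestral_pool(n_sites, n_ref, mu, seed):
    """Equilibrium site frequencies at the reference size (LRU-cached)."""
    key = (int(n_sites), int(n_ref), float(mu), _seed_key(seed))
    if key in _POOL_CACHE:
        _POOL_CACHE[key] = _POOL_CACHE.pop(key)  # refresh LRU position
    else:
        if len(_POOL_CACHE) >= _POOL_CACHE_MAX:
            _POOL_CACHE.pop(next(iter(_POOL_CACHE)))
        rng = np.random.default_rng(list(key[3]) + [911])
        p = np.zeros(n_sites)
        n2 = 2 * n_ref
        for _ in range(8 * n_ref):
            p = rng.binomial(n2, mutate_freqs(p, mu)) / n2
        _POOL_CACHE[key] = p
    return _POOL_CACHE[key]


def expected_sfs(model: DemographicModel, n1, n2, n_replicate_sites, seed,
                 n_ref=60, theta=0.01, smoothing=0.5) -> SFS:
    """Monte-Carlo expected joint SFS under the scaled model.

    Simulates ``n_replicate_sites`` independent neutral sites forward at
    reference ancestral size ``n_ref`` (theta-preserving desk scale), samples
    ``n1`` cultivated and ``n2`` weedy alleles, folds, masks singletons and
    normalizes to probabilities over unmasked entries. Axis 1 = cultivated,
    axis 2 = weedy. Seed-reproducible.

    ``smoothing`` adds a pseudo-count to every unmasked cell before
    normalizing. A finite-site Monte-Carlo estimate leaves rare cells empty
    by chance; without smoothing those cells hit the log-floor and dominate
    the likelihood noise (set to 0 for the raw estimator).
    """
    mu = theta / (4.0 * n_ref)
    p0 = _ancestral_pool(n_replicate_sites, n_ref, mu, seed)
    rng = np.random.default_rng(list(_seed_key(seed)) + [191])

    nu_w = model.params["nu_w"]
    tau = model.params["tau"]
    N_a = int(n_ref)
    N_w = max(2, round(nu_w * n_ref))
    T = round(tau * 2 * n_ref)
    m = min(0.499, model.params.get("M", 0.0) / (2.0 * n_ref))

    p_c = p0.copy()
    if model.has_bottleneck:
        N_b = max(2, round(model.params["nu_b"] * n_ref))
        T_b = round(model.params["tau_b"] * 2 * n_ref)
        p_w = rng.binomial(2 * N_b, p_c) / (2 * N_b)
        n2a, n2b = 2 * N_a, 2 * N_b
        for _ in range(T_b):
            p_c = rng.binomial(n2a, mutate_freqs(p_c, mu)) / n2a
            p_w = rng.binomial(n2b, mutate_freqs(p_w, mu)) / n2b
    else:
        p_w = rng.binomial(2 * N_w, p_c) / (2 * N_w)
    n2a, n2w = 2 * N_a, 2 * N_w
    for _ in range(T):
        pc1 = mutate_freqs(p_c, mu)
        pw1 = mutate_freqs(p_w, mu)
        pc2 = (1.0 - m) * pc1 + m * pw1
        pw2 = (1.0 - m) * pw1 + m * pc1
        p_c = rng.binomial(n2a, pc2) / n2a
        p_w = rng.binomial(n2w, pw2) / n2w

    j1 = rng.binomial(n1, p_c)
    j2 = rng.binomial(n2, p_w)
    flat = np.bincount(j1 * (n2 + 1) + j2, minlength=(n1 + 1) * (n2 + 1))
    counts = flat.reshape(n1 + 1, n2 + 1).astype(float)
    sfs = mask_singletons(fold_sfs(SFS(counts)))
    if smoothing:
        support = folded_support(sfs.counts.shape) & ~sfs.mask
        sfs = SFS(
            np.where(support, sfs.counts + smoothing, sfs.counts),
            folded=sfs.folded,
            mask=sfs.mask,
        )
    return sfs.normalized()


def prepare_observed_sfs(matrix, cultivated_samples, weedy_samples, n1, n2) -> SFS:
    """Observed joint SFS: build, project to (n1, n2), fold, mask singletons.

    Axis order matches ``expected_sfs`` (cultivated first).
    """
    raw = build_sfs(matrix, cultivated_samples, weedy_samples)
    proj = project_sfs(raw, (n1, n2))
    return mask_singletons(fold_sfs(proj))


def composite_log_likelihood(observed: SFS, expected: SFS) -> float:
    """Multinomial composite LL: sum over unmasked cells of obs * log(exp).

    Expected probabilities are floored at 1e-12 to avoid log(0).
    """
    if observed.counts.shape != expected.counts.shape:
        raise InputError("observed/expected SFS shapes differ")
    if observed.folded != expected.folded:
        raise InputError("observed/expected folding differs")
    if not np.array_equal(observed.mask, expected.mask):
        raise InputError("observed/expected masks differ")
    keep = ~observed.mask
    exp = np.maximum(expected.counts[keep], 1e-12)
    return float(np.sum(observed.counts[keep] * np.log(exp)))


# ---------------------------------------------------------------------------
# Fitting and model comparison
# ---------------------------------------------------------------------------


def _resolve_bounds(model_id, bounds):
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    return [merged[name] for name in PARAM_NAMES[model_id]]


def fit_model(
    observed: SFS,
    model_id,
    n_runs=20,
    optimizer_budget=100,
    bounds=None,
    seed=0,
    n_expected_sites=10_000,
    n_ref=60,
    theta=0.01,
    extra_starts=None,
) -> FitResult:
    """Multi-start Nelder-Mead fit of one model to an observed joint SFS.

    Each run draws a log-uniform random start within bounds and locally
    optimizes the composite LL in log-parameter space under a fixed
    evaluation budget. One site-simulation seed (derived from ``seed``) is
    shared by every parameter evaluation of every run — common random
    numbers — so the likelihood surface is deterministic for the whole fit
    and directly comparable across models fitted with the same seed.
    Headline parameters are the per-parameter median over the top decile of
    runs by LL. ``extra_starts`` (list of param dicts) adds deterministic
    warm starts after the random ones; each is also kept unpolished as a
    candidate row.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    names = PARAM_NAMES[model_id]
    bnds = _resolve_bounds(model_id, bounds)
    n1, n2 = observed.n
    lo = np.log10([b[0] for b in bnds])
    hi = np.log10([b[1] for b in bnds])
    eval_seed = (int(seed),)

    def surface_ll(xc):
        params = dict(zip(names, 10.0**xc))
        model = DemographicModel(model_id, params)
        exp = expected_sfs(
            model, n1, n2, n_expected_sites, eval_seed, n_ref=n_ref, theta=theta
        )
        return composite_log_likelihood(observed, exp)

    rows = []
    starts = []
    for run in range(n_runs):
        start_rng = np.random.default_rng([int(seed), run, 23])
        starts.append(("random", start_rng.uniform(lo, hi)))
    for extra in extra_starts or []:
        # evaluate the embedding exactly as given (it may sit on a nested
        # boundary such as M = 0, outside the log-search box) so a nested
        # model's optimum is reachable verbatim ...
        model = DemographicModel(model_id, dict(extra))
        exp = expected_sfs(
            model, n1, n2, n_expected_sites, eval_seed, n_ref=n_ref, theta=theta
        )
        raw = {"run": -1, "kind": "warm_raw",
               "ll": composite_log_likelihood(observed, exp)}
        raw.update({f"start_{k}": extra[k] for k in names})
        raw.update({k: extra[k] for k in names})
        rows.append(raw)
        # ... and also polish from its in-bounds projection
        x = np.clip(
            np.log10([max(extra[k], bnd[0]) for k, bnd in zip(names, bnds)]),
            lo, hi,
        )
        starts.append(("warm", x))
    for run, (kind, x0) in enumerate(starts):
        best = {"ll": surface_ll(x0), "x": x0.copy()}

        def objective(x):
            xc = np.clip(x, lo, hi)
            ll = surface_ll(xc)
            if ll > best["ll"]:
                best["ll"] = ll
                best["x"] = xc.copy()
            return -ll

        # initial simplex spanning ~0.25 decades per parameter: the default
        # (5% of coordinate) is far too local for log-scale exploration
        simplex = [x0]
        for d in range(len(names)):
            v = x0.copy()
            step = 0.25 if x0[d] + 0.25 <= hi[d] else -0.25
            v[d] = np.clip(v[d] + step, lo[d], hi[d])
            simplex.append(v)
        minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": int(optimizer_budget),
                "xatol": 1e-3,
                "fatol": 1e-3,
                "initial_simplex": np.array(simplex),
            },
        )
        row = {"run": run, "kind": kind, "ll": best["ll"]}
        row.update({f"start_{k}": 10.0**v for k, v in zip(names, x0)})
        row.update({k: 10.0**v for k, v in zip(names, best["x"])})
        rows.append(row)
    runs = pd.DataFrame(rows)
    if not np.isfinite(runs["ll"]).any():
        raise InputError(f"all {n_runs} runs non-finite for {model_id}")
    runs = runs.sort_values("ll", ascending=False).reset_index(drop=True)
    top = runs.head(max(1, math.ceil(n_runs / 10)))
    best_row = runs.iloc[0]
    return FitResult(
        model_id=model_id,
        best_params={k: float(best_row[k]) for k in names},
        max_ll=float(best_row["ll"]),
        runs=runs,
        median_params={k: float(top[k].median()) for k in names},
    )


def compare_models(
    observed: SFS, model_ids=MODEL_IDS, rescore_sites=30_000, **fit_kwargs
):
    """Fit several models and rank them by best composite log-likelihood.

    Returns ``(ranking DataFrame, dict of FitResult)``. The same seed (hence
    the same per-run random-number streams) is used for every model, so
    expected-spectrum Monte-Carlo noise is common across models. Before
    ranking, each model's best parameters are re-scored on a finer
    Monte-Carlo expectation (``rescore_sites`` sites, fresh common seed) so
    that the ranking does not reward overfitting the fit-time noise; pass
    ``rescore_sites=None`` to rank on the raw fitted likelihoods.
    """
    if len(model_ids) < 2:
        raise ParameterError("compare_models needs >= 2 models")
    n1, n2 = observed.n
    seed = fit_kwargs.get("seed", 0)
    n_ref = fit_kwargs.get("n_ref", 60)
    theta = fit_kwargs.get("theta", 0.01)

    def rescore(mid, fit):
        """Best candidate of a fit on fine common-seed evaluations.

        The cheap fit-time surface proposes candidates (one per run), finer
        surfaces decide, so the ranking does not reward overfitting the
        fit-time Monte-Carlo noise. Stage 1 screens all candidates at
        ``rescore_sites`` sites with a per-comparison seed; stage 2 scores
        each model's top two survivors at 4x that size with a fixed seed.
        """
        names = PARAM_NAMES[mid]
        stage1 = []
        for _, row in fit.runs.iterrows():
            params = {k: float(row[k]) for k in names}
            exp = expected_sfs(
                DemographicModel(mid, params),
                n1, n2, rescore_sites, (int(seed), 977),
                n_ref=n_ref, theta=theta,
            )
            stage1.append((composite_log_likelihood(observed, exp), params))
        stage1.sort(key=lambda t: t[0], reverse=True)
        best_ll, best_params = -np.inf, stage1[0][1]
        for _, params in stage1[:2]:
            exp = expected_sfs(
                DemographicModel(mid, params),
                n1, n2, 4 * rescore_sites, (977,),
                n_ref=n_ref, theta=theta,
            )
            ll = composite_log_likelihood(observed, exp)
            if ll > best_ll:
                best_ll, best_params = ll, params
        return best_ll, best_params

    # fit in nesting order (fewest parameters first) and warm-start every
    # model from the best (rescored) fits of the models it nests, alongside
    # its random starts; this keeps the empirical LL ordering consistent
    # with the analytical nesting hierarchy under a finite optimizer budget
    fits, scored = {}, {}
    for mid in sorted(model_ids, key=lambda m: len(PARAM_NAMES[m])):
        warm = []
        for done_id, (_ll, done_params) in scored.items():
            if set(PARAM_NAMES[done_id]) <= set(PARAM_NAMES[mid]):
                # exact nesting values: a bottleneck of the recovered size
                # with zero duration and zero migration reproduce the nested
                # model's dynamics (and its likelihood) verbatim
                embedded = dict(done_params)
                if "nu_b" in PARAM_NAMES[mid] and "nu_b" not in embedded:
                    embedded["nu_b"] = embedded["nu_w"]
                if "tau_b" in PARAM_NAMES[mid] and "tau_b" not in embedded:
                    embedded["tau_b"] = 0.0
                missing = set(PARAM_NAMES[mid]) - set(PARAM_NAMES[done_id])
                if "M" in PARAM_NAMES[mid] and "M" not in embedded:
                    embedded["M"] = 0.0
                warm.append(embedded)
                if missing == {"M"}:
                    # migration is the hardest axis to discover from random
                    # starts: profile it from the nested no-migration optimum
                    for m_start in (1.0, 4.0):
                        warm.append(dict(embedded, M=m_start))
        fit = fit_model(observed, mid, extra_starts=warm, **fit_kwargs)
        fits[mid] = fit
        scored[mid] = rescore(mid, fit) if rescore_sites else (fit.max_ll, fit.best_params)

    rows = [
        {"model_id": mid, "best_ll": scored[mid][0], "n_params": len(PARAM_NAMES[mid])}
        for mid in model_ids
    ]
    table = pd.DataFrame(rows).sort_values(
        ["best_ll", "n_params"], ascending=[False, True]
    )
    table["delta_ll"] = table["best_ll"].max() - table["best_ll"]
    return table.reset_index(drop=True), fits


def load_config(path) -> dict:
    """Read a JSON config with optional ``bounds``, ``n_ref`` and ``theta``.

    ``bounds`` maps parameter names to [low, high]; unknown keys rejected.
    """
    import json

    with open(path) as fh:
        cfg = json.load(fh)
    unknown = set(cfg) - {"bounds", "n_ref", "theta"}
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    bounds = cfg.get("bounds", {})
    bad = set(bounds) - set(DEFAULT_BOUNDS)
    if bad:
        raise ParameterError(f"unknown bound parameters: {sorted(bad)}")
    cfg["bounds"] = {k: (float(v[0]), float(v[1])) for k, v in bounds.items()}
    return cfg


def bootstrap_ci(observed, model_id, n_boot=100, **fit_kwargs):
    """Hook for bootstrap confidence intervals on fitted parameters.

    Deliberately not implemented: resampling the SFS and refitting is
    prohibitively slow with the Monte-Carlo expectation backend.
    """
    raise NotImplementedError(
        "bootstrap confidence intervals are a documented extension point"
    )


def preset_demography(model_id, N_a):
    """Concrete simulator parameters for a preset model at ancestral size N_a."""
    from .sim import DemographyParams  # local import avoids cycles in docs

    p = MODEL_PRESETS[model_id]
    nu_b = p.get("nu_b", p["nu_w"])
    tau_b = p.get("tau_b", 0.0)
    return DemographyParams(
        N_a=int(N_a),
        N_b=max(2, round(nu_b * N_a)),
        N_w=max(2, round(p["nu_w"] * N_a)),
        T_b=round(tau_b * 2 * N_a) if model_id.startswith("BN") else 0,
        T=round(p["tau"] * 2 * N_a),
        m=p.get("M", 0.0) / (2.0 * N_a),
    )
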