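"""Gaussian-process Bayesian optimization with expected improvement.

Used to tune the CNN hyperparameters: a Matern-5/2 GP surrogate is fit to
the observed (configuration, objective) pairs in a unit-cube encoding of the
search space, and each acquisition maximizes expected improvement over a
seeded random candidate pool. Defaults follow the search protocol used for
the network: 30 initial random points, then 300 sequential acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple, Union

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

#: space entries: ("real", lo, hi) | ("int", lo, hi) | ("choice", [options...])
SpaceSpec = Dict[str, Tuple]


@dataclass
class HpoConfig:
    n_initial: int = 30
    n_acquisitions: int = 300
    objective: str = "val_spearman"     # or "val_auc"; maximized
    n_candidates: int = 512             # EI candidate pool per acquisition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if self.n_acquisitions < 0:
            raise ValueError("n_acquisitions must be >= 0")


@dataclass
class HpoTrace:
    configs: List[dict] = field(default_factory=list)
    values: List[float] = field(default_factory=list)

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.values))

    @property
    def best_config(self) -> dict:
        return self.configs[self.best_index]

    @property
    def best_value(self) -> float:
        return float(self.values[self.best_index])


def _validate_space(space: SpaceSpec) -> None:
    if not space:
        raise ValueError("empty search space")
    for name, spec in space.items():
        kind = spec[0]
        if kind not in ("real", "int", "choice"):
            raise ValueError(f"{name}: unknown dimension kind {kind!r}")
        if kind in ("real", "int") and not spec[1] < spec[2]:
            raise ValueError(f"{name}: lower bound must be < upper bound")
        if kind == "choice" and len(spec[1]) < 1:
            raise ValueError(f"{name}: empty choice list")


def _sample_unit(space: SpaceSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.random((n, len(space)))


def _decode(space: SpaceSpec, u: np.ndarray) -> dict:
    cfg = {}
    for (name, spec), x in zip(space.items(), u):
        kind = spec[0]
        if kind == "real":
            cfg[name] = spec[1] + x * (spec[2] - spec[1])
        elif kind == "int":
            cfg[name] = int(spec[1] + np.floor(x * (spec[2] - spec[1] + 1 - 1e-12)))
        else:
            opts = spec[1]
            cfg[name] = opts[min(int(x * len(opts)), len(opts) - 1)]
    return cfg


def expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def bayesian_hpo(
    space: SpaceSpec,
    objective: Callable[[dict], float],
    cfg: HpoConfig = HpoConfig(),
) -> Tuple[dict, HpoTrace]:
    """Maximize ``objective`` over ``space``; returns (best config, trace).

    Fully deterministic given ``cfg.seed``: initial designs, GP fitting and
    candidate pools all derive from one seeded generator.
    """
    _validate_space(space)
    rng = np.random.default_rng(cfg.seed)
    trace = HpoTrace()

    U = _sample_unit(space, rng, cfg.n_initial)
    for u in U:
        c = _decode(space, u)
        trace.configs.append(c)
        trace.values.append(float(objective(c)))
    X = list(U)

    kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(len(space), 0.25), nu=2.5) \
        + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))
    for _ in range(cfg.n_acquisitions):
        y = np.array(trace.values)
        y_mean, y_std = y.mean(), y.std() or 1.0
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, random_state=cfg.seed, n_restarts_optimizer=0
        )
        with warnings.catch_warnings():
            # kernel hyperparameter refits may stop early; the surrogate is
            # still usable for acquisition ranking
            warnings.simplefilter("ignore")
            gp.fit(np.array(X), (y - y_mean) / y_std)
        cand = _sample_unit(space, rng, cfg.n_candidates)
        mu, sigma = gp.predict(cand, return_std=True)
        ei = expected_improvement(mu, sigma, (y.max() - y_mean) / y_std)
        u = cand[int(np.argmax(ei))]
        c = _decode(space, u)
        trace.configs.append(c)
        trace.values.append(float(objective(c)))
        X.append(u)

    return trace.best_config, trace


def cv_objective(samples, split, base_cfg, metric: str = "auto"):
    """Objective factory: hyperparameter dict -> mean K-fold CV validation
    metric of the CNN (5 folds by default), for use with bayesian_hpo."""
    import dataclasses

    from .model import cross_validate

    def objective(hp: dict) -> float:
        cfg = dataclasses.replace(base_cfg, **hp)
        rep = cross_validate(samples, split, cfg, n_folds=split.cv_folds_hpo)
        if cfg.task == "classification":
            return rep.auc if rep.auc is not None else -np.inf
        return rep.spearman if rep.spearman is not None else -np.inf

    return objective
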