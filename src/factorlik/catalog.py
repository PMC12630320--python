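"""Catalog of matched-comparison models with per-block nuisance parameters.

Every model describes outcomes in blocks of size ``m`` (pairs unless stated
otherwise), whose distribution is known up to an interest parameter (treatment
effect, hazard ratio, ...) and one nuisance parameter per block, optionally
with further parameters shared across blocks.  The catalog carries both a
symbolic density, used by the factorisation machinery, and a sampler, used by
the verification and simulation modules.

Catalog entries
---------------
``normal_pair``          normal pairs, common variance (interest), per-pair mean
``logistic_pair``        binary pairs, treatment log-odds shift
``exp_hazard_pair``      exponential pairs with constant hazard ratio ``psi**2``
``exp_triplet``          exponential triplets, two relative rate parameters
``weibull_pair``         Weibull pairs, shared shape plus per-pair rate
``cauchy_pair``          Cauchy pairs, common location per pair, interest scale
``exp_reg``              exponential regression, shared scale nuisance
``loglogistic_reg``      log-logistic accelerated-life regression
``exp_mean_shift_pair``  exponential pairs with means ``mu -/+ psi``
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
import sympy as sp
import yaml
from scipy import stats

__all__ = [
    "ModelSpec",
    "PairedSample",
    "UnknownModelError",
    "ParamDomainError",
    "make_model",
    "sample_blocks",
    "catalog_names",
    "arm_distribution",
    "read_table",
    "write_table",
    "load_config",
    "sample_from_config",
]


class UnknownModelError(KeyError):
    """Requested model name is not in the catalog."""


class ParamDomainError(ValueError):
    """A parameter value lies outside its admissible domain."""


@dataclass(frozen=True)
class ModelSpec:
    """A parametric block model.

    ``marginals[j]`` is the density of the ``j``-th outcome in a block; block
    outcomes are independent so the joint density is their product.  For the
    binary model the "density" is a probability mass function and ``support``
    is the discrete set ``{0, 1}`` encoded as ``("discrete", (0, 1))``.
    """

    name: str
    outcome_symbols: tuple
    marginals: tuple
    interest: tuple
    nuisances: tuple
    support: tuple
    param_domains: dict
    block_size: int = 2
    covariates: tuple = ()
    discrete: bool = False
    # joint constraints as sympy relational expressions, e.g. -1 < lambda*psi < 1
    constraints: tuple = ()
    meta: dict = dc_field(default_factory=dict)

    @property
    def density(self):
        """Joint symbolic density of one block (product of independents)."""
        return sp.Mul(*self.marginals)

    @property
    def parameters(self):
        return tuple(self.interest) + tuple(self.nuisances)

    def validate_params(self, values: Mapping) -> None:
        """Raise :class:`ParamDomainError` if any value is out of domain.

        ``values`` maps symbols (or their string names) to numbers.
        """
        byname = {str(k): v for k, v in values.items()}
        for sym, (lo, hi) in self.param_domains.items():
            v = byname.get(str(sym))
            if v is None:
                continue
            if not (lo < v < hi):
                raise ParamDomainError(
                    f"{sym} = {v} outside domain ({lo}, {hi}) for model {self.name}"
                )
        for cons in self.constraints:
            syms = list(cons.free_symbols)
            if all(str(s) in byname for s in syms):
                ok = cons.subs({s: byname[str(s)] for s in syms})
                if not bool(ok):
                    raise ParamDomainError(
                        f"constraint {cons} violated by {byname} for model {self.name}"
                    )

    def arm_labels(self) -> tuple:
        if self.block_size == 1:
            return ("Y",)
        if self.block_size == 2:
            return ("T", "C")
        return tuple(f"arm{j + 1}" for j in range(self.block_size))


@dataclass
class PairedSample:
    """Blocked outcomes in long format: one row per (block, arm)."""

    block_ids: np.ndarray
    arms: np.ndarray
    values: np.ndarray
    covariates: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.block_ids = np.asarray(self.block_ids)
        self.arms = np.asarray(self.arms)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.block_ids) == len(self.arms) == len(self.values)):
            raise ValueError("block_ids, arms and values must have equal length")

    @property
    def n_blocks(self) -> int:
        return len(np.unique(self.block_ids))

    def by_arm(self, arm: str) -> np.ndarray:
        """Values of one arm, ordered by block id."""
        mask = self.arms == arm
        order = np.argsort(self.block_ids[mask], kind="stable")
        return self.values[mask][order]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"block_id": self.block_ids, "arm": self.arms, "value": self.values}
        )
        if self.covariates is not None:
            X = np.atleast_2d(self.covariates)
            for j in range(X.shape[1]):
                df[f"x{j + 1}"] = X[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "PairedSample":
        xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
        X = df[xcols].to_numpy() if xcols else None
        return cls(
            block_ids=df["block_id"].to_numpy(),
            arms=df["arm"].to_numpy(),
            values=df["value"].to_numpy(),
            covariates=X,
            meta=meta or {},
        )


def read_table(path, sep=None) -> PairedSample:
    """Read a delimited table with header ``block_id,arm,value[,x1..xp]``."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = {"block_id", "arm", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"table {path} lacks required columns {sorted(missing)}")
    return PairedSample.from_frame(df)


def write_table(sample: PairedSample, path, sep=",") -> None:
    sample.to_frame().to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# catalog construction
# --------------------------------------------------------------------------

_PSI = sp.Symbol("psi", positive=True)
_LAM = sp.Symbol("lambda", positive=True)


def _exp_pdf(x, rate):
    return rate * sp.exp(-rate * x)


def _build_entry(name: str, shared: Mapping) -> ModelSpec:
    shared = {str(k): v for k, v in (shared or {}).items()}
    psi, lam = _PSI, _LAM
    if name == "exp_hazard_pair":
        t, c = sp.symbols("t c", positive=True)
        return ModelSpec(
            name=name,
            outcome_symbols=(t, c),
            marginals=(_exp_pdf(t, lam * psi), _exp_pdf(c, lam / psi)),
            interest=(psi,),
            nuisances=(lam,),
            support=((0, sp.oo), (0, sp.oo)),
            param_domains={psi: (0, np.inf), lam: (0, np.inf)},
        )
    if name == "exp_mean_shift_pair":
        t, c = sp.symbols("t c", positive=True)
        psi_r = sp.Symbol("psi", real=True)  # psi may exceed 1/lambda in sign only
        rate_t = lam / (1 - lam * psi_r)
        rate_c = lam / (1 + lam * psi_r)
        return ModelSpec(
            name=name,
            outcome_symbols=(t, c),
            marginals=(_exp_pdf(t, rate_t), _exp_pdf(c, rate_c)),
            interest=(psi_r,),
            nuisances=(lam,),
            support=((0, sp.oo), (0, sp.oo)),
            param_domains={lam: (0, np.inf)},
            constraints=(sp.Abs(lam * psi_r) < 1,),
        )
    if name == "weibull_pair":
        t, c = sp.symbols("t c", positive=True)
        alpha = sp.Symbol("alpha", positive=True)
        m1 = alpha * lam * psi * t ** (alpha - 1) * sp.exp(-lam * psi * t**alpha)
        m2 = alpha * (lam / psi) * c ** (alpha - 1) * sp.exp(-(lam / psi) * c**alpha)
        spec = ModelSpec(
            name=name,
            outcome_symbols=(t, c),
            marginals=(m1, m2),
            interest=(psi,),
            nuisances=(lam, alpha),  # per-block lambda, shared shape alpha
            support=((0, sp.oo), (0, sp.oo)),
            param_domains={psi: (0, np.inf), lam: (0, np.inf), alpha: (0, np.inf)},
        )
        if "alpha" in shared:
            spec.validate_params({"alpha": shared["alpha"]})
            object.__setattr__(spec, "meta", {"alpha": float(shared["alpha"])})
        return spec
    if name == "cauchy_pair":
        t, c = sp.symbols("t c", real=True)
        lam_r = sp.Symbol("lambda", real=True)
        m = lambda x: 1 / (sp.pi * psi * (1 + ((x - lam_r) / psi) ** 2))
        return ModelSpec(
            name=name,
            outcome_symbols=(t, c),
            marginals=(m(t), m(c)),
            interest=(psi,),
            nuisances=(lam_r,),
            support=((-sp.oo, sp.oo), (-sp.oo, sp.oo)),
            param_domains={psi: (0, np.inf)},
        )
    if name == "normal_pair":
        y1, y2 = sp.symbols("y1 y2", real=True)
        mu = sp.Symbol("mu", real=True)
        sigma2 = sp.Symbol("sigma2", positive=True)
        m = lambda x: sp.exp(-((x - mu) ** 2) / (2 * sigma2)) / sp.sqrt(
            2 * sp.pi * sigma2
        )
        return ModelSpec(
            name=name,
            outcome_symbols=(y1, y2),
            marginals=(m(y1), m(y2)),
            interest=(sigma2,),
            nuisances=(mu,),
            support=((-sp.oo, sp.oo), (-sp.oo, sp.oo)),
            # closed at zero: sigma2 = 0 is the degenerate point-mass pair
            param_domains={sigma2: (-1e-300, np.inf)},
        )
    if name == "logistic_pair":
        t, c = sp.symbols("t c", integer=True, nonnegative=True)
        lam_r = sp.Symbol("lambda", real=True)
        psi_r = sp.Symbol("psi", real=True)
        p_t = sp.exp(lam_r + psi_r) / (1 + sp.exp(lam_r + psi_r))
        p_c = sp.exp(lam_r) / (1 + sp.exp(lam_r))
        return ModelSpec(
            name=name,
            outcome_symbols=(t, c),
            marginals=(p_t**t * (1 - p_t) ** (1 - t), p_c**c * (1 - p_c) ** (1 - c)),
            interest=(psi_r,),
            nuisances=(lam_r,),
            support=(("discrete", (0, 1)), ("discrete", (0, 1))),
            param_domains={},
            discrete=True,
        )
    if name == "exp_triplet":
        x1, x2, x3 = sp.symbols("x1 x2 x3", positive=True)
        psi1, psi2 = sp.symbols("psi1 psi2", positive=True)
        return ModelSpec(
            name=name,
            outcome_symbols=(x1, x2, x3),
            marginals=(
                _exp_pdf(x1, lam * psi1),
                _exp_pdf(x2, lam * psi2),
                _exp_pdf(x3, lam),
            ),
            interest=(psi1, psi2),
            nuisances=(lam,),
            support=((0, sp.oo), (0, sp.oo), (0, sp.oo)),
            param_domains={
                psi1: (0, np.inf),
                psi2: (0, np.inf),
                lam: (0, np.inf),
            },
            block_size=3,
        )
    if name == "exp_reg":
        # one unit per "block"; pairs (Y_i, Y_1) are formed downstream, so the
        # symbolic density is that of a generic pair with covariates xi, x1
        yi, y1 = sp.symbols("yi y1", positive=True)
        xi, x1 = sp.symbols("xi x1", real=True)
        psi_r = sp.Symbol("psi", real=True)
        ri = 1 / (lam * sp.exp(xi * psi_r))
        r1 = 1 / (lam * sp.exp(x1 * psi_r))
        return ModelSpec(
            name=name,
            outcome_symbols=(yi, y1),
            marginals=(_exp_pdf(yi, ri), _exp_pdf(y1, r1)),
            interest=(psi_r,),
            nuisances=(lam,),
            support=((0, sp.oo), (0, sp.oo)),
            param_domains={lam: (0, np.inf)},
            block_size=1,
            covariates=(xi, x1),
        )
    if name == "loglogistic_reg":
        yi, y1 = sp.symbols("yi y1", positive=True)
        xi, x1 = sp.symbols("xi x1", real=True)
        psi_r = sp.Symbol("psi", real=True)
        beta = sp.Symbol("beta", positive=True)

        def ll_pdf(y, x):
            a = lam * sp.exp(x * psi_r)
            return (beta / a) * (y / a) ** (beta - 1) / (1 + (y / a) ** beta) ** 2

        spec = ModelSpec(
            name=name,
            outcome_symbols=(yi, y1),
            marginals=(ll_pdf(yi, xi), ll_pdf(y1, x1)),
            interest=(psi_r,),
            nuisances=(lam, beta),
            support=((0, sp.oo), (0, sp.oo)),
            param_domains={lam: (0, np.inf), beta: (0, np.inf)},
            block_size=1,
            covariates=(xi, x1),
        )
        if "beta" in shared:
            spec.validate_params({"beta": shared["beta"]})
            object.__setattr__(spec, "meta", {"beta": float(shared["beta"])})
        return spec
    raise UnknownModelError(name)


def catalog_names() -> tuple:
    return (
        "normal_pair",
        "logistic_pair",
        "exp_hazard_pair",
        "exp_triplet",
        "weibull_pair",
        "cauchy_pair",
        "exp_reg",
        "loglogistic_reg",
        "exp_mean_shift_pair",
    )


def make_model(name: str, shared_params: Mapping | None = None) -> ModelSpec:
    """Build a catalog model, optionally fixing shared parameters.

    Parameters given in ``shared_params`` (e.g. the Weibull shape ``alpha`` or
    the log-logistic shape ``beta``) are validated against their domain and
    recorded in ``meta``; the symbolic density keeps them symbolic so the
    factorisation machinery can differentiate against them.
    """
    if name not in catalog_names():
        raise UnknownModelError(name)
    return _build_entry(name, shared_params or {})


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


class _Degenerate:
    """Point mass at loc; closes the sigma2 -> 0 limit of the normal pair."""

    def __init__(self, loc):
        self.loc = np.asarray(loc, dtype=float)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.loc.copy()
        return np.broadcast_to(self.loc, (size,)).copy()


def arm_distribution(model: ModelSpec, arm: str, psi, lam, shared=None, x=None):
    """Frozen scipy distribution of one arm's outcome.

    ``psi`` is the interest-parameter value (``sigma2`` for ``normal_pair``
    where ``lam`` plays the per-pair mean; a pair ``(psi1, psi2)`` for the
    triplet model).  ``lam`` may be an array of per-block values.
    """
    shared = shared or {}
    lam = np.asarray(lam, dtype=float)
    name = model.name
    if name == "exp_hazard_pair":
        rate = lam * psi if arm == "T" else lam / psi
        return stats.expon(scale=1.0 / rate)
    if name == "exp_mean_shift_pair":
        rho = lam * psi
        if np.any(np.abs(rho) >= 1):
            raise ParamDomainError("need |lambda*psi| < 1")
        scale = (1 - rho) / lam if arm == "T" else (1 + rho) / lam
        return stats.expon(scale=scale)
    if name == "weibull_pair":
        alpha = shared.get("alpha", model.meta.get("alpha", 1.0))
        rate = lam * psi if arm == "T" else lam / psi
        return stats.weibull_min(c=alpha, scale=rate ** (-1.0 / alpha))
    if name == "cauchy_pair":
        return stats.cauchy(loc=lam, scale=psi)
    if name == "normal_pair":
        if psi == 0:
            return _Degenerate(lam)
        return stats.norm(loc=lam, scale=np.sqrt(psi))
    if name == "logistic_pair":
        eta = lam + psi if arm == "T" else lam
        return stats.bernoulli(p=1.0 / (1.0 + np.exp(-eta)))
    if name == "exp_triplet":
        psi1, psi2 = psi
        rate = {"arm1": lam * psi1, "arm2": lam * psi2, "arm3": lam}[arm]
        return stats.expon(scale=1.0 / rate)
    if name == "exp_reg":
        if x is None:
            raise ValueError("exp_reg requires covariate values x")
        return stats.expon(scale=lam * np.exp(np.asarray(x) * psi))
    if name == "loglogistic_reg":
        if x is None:
            raise ValueError("loglogistic_reg requires covariate values x")
        beta = shared.get("beta", model.meta.get("beta", 1.0))
        return stats.fisk(c=beta, scale=lam * np.exp(np.asarray(x) * psi))
    raise UnknownModelError(name)


def _resolve_nuisance(nuisance_gen, b: int, rng: np.random.Generator) -> np.ndarray:
    """Turn a nuisance rule into a length-b vector of lambda values.

    Accepted forms: scalar, sequence of length b, callable ``(b, rng)``, or a
    mapping ``{"kind": "fixed"|"lognormal"|"normal"|"grid_lognormal", ...}``.
    Grid kinds give deterministic equally spaced quantiles, matching the
    fixed-constants view of the nuisance parameters.
    """
    if callable(nuisance_gen):
        lam = np.asarray(nuisance_gen(b, rng), dtype=float)
    elif np.isscalar(nuisance_gen):
        lam = np.full(b, float(nuisance_gen))
    elif isinstance(nuisance_gen, Mapping):
        kind = nuisance_gen.get("kind", "fixed")
        if kind == "fixed":
            vals = np.asarray(nuisance_gen["values"], dtype=float)
            lam = np.resize(vals, b)
        elif kind == "lognormal":
            lam = rng.lognormal(
                nuisance_gen.get("mean", 0.0), nuisance_gen.get("sigma", 0.5), size=b
            )
        elif kind == "normal":
            lam = rng.normal(
                nuisance_gen.get("mean", 0.0), nuisance_gen.get("sigma", 1.0), size=b
            )
        elif kind == "grid_lognormal":
            q = (np.arange(b) + 0.5) / b
            lam = stats.lognorm(
                s=nuisance_gen.get("sigma", 0.5),
                scale=np.exp(nuisance_gen.get("mean", 0.0)),
            ).ppf(q)
        elif kind == "grid_normal":
            q = (np.arange(b) + 0.5) / b
            lam = stats.norm(
                loc=nuisance_gen.get("mean", 0.0), scale=nuisance_gen.get("sigma", 1.0)
            ).ppf(q)
        else:
            raise ValueError(f"unknown nuisance kind {kind!r}")
    else:
        lam = np.asarray(nuisance_gen, dtype=float)
        if lam.shape != (b,):
            raise ValueError(f"nuisance vector must have length b={b}")
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite nuisance values")
    return lam


def sample_blocks(
    model: ModelSpec,
    b: int,
    nuisance_gen,
    psi,
    seed: int,
    shared: Mapping | None = None,
    covariates=None,
) -> PairedSample:
    """Draw ``b`` independent blocks from a catalog model.

    Reproducible given ``seed``; a single deterministic stream drives the
    whole sample (per-arm vectorised draws).  For the regression models each
    unit is its own block and ``covariates`` supplies x_i (default: standard
    normal draws, recorded in the output).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    rng = np.random.default_rng(seed)
    lam = _resolve_nuisance(nuisance_gen, b, rng)
    shared = dict(shared or {})
    shared = {**model.meta, **shared}

    # domain validation on the extremes of the nuisance vector
    psi_vals = psi if isinstance(psi, (tuple, list)) else (psi,)
    for nm, v in zip([str(s) for s in model.interest], psi_vals):
        model.validate_params({nm: v})
    lam_name = str(model.nuisances[0])
    for v in (lam.min(), lam.max()):
        model.validate_params({lam_name: v})
    for cons_probe in (lam.min(), lam.max()):
        model.validate_params({lam_name: cons_probe, str(model.interest[0]): psi_vals[0]})

    if model.block_size == 1:
        if covariates is None:
            covariates = rng.normal(size=b)
        x = np.asarray(covariates, dtype=float)
        dist = arm_distribution(model, "Y", psi, lam, shared=shared, x=x)
        vals = dist.rvs(size=b, random_state=rng)
        return PairedSample(
            block_ids=np.arange(1, b + 1),
            arms=np.array(["Y"] * b),
            values=vals,
            covariates=x.reshape(-1, 1),
            meta={
                "model": model.name,
                "psi": psi,
                "seed": seed,
                "lambda": lam,
                **shared,
            },
        )

    arms = model.arm_labels()
    blocks, labels, values = [], [], []
    for arm in arms:
        dist = arm_distribution(model, arm, psi, lam, shared=shared)
        vals = dist.rvs(size=b, random_state=rng)
        blocks.append(np.arange(1, b + 1))
        labels.append(np.array([arm] * b))
        values.append(vals)
    sample = PairedSample(
        block_ids=np.concatenate(blocks),
        arms=np.concatenate(labels),
        values=np.concatenate(values),
        meta={"model": model.name, "psi": psi, "seed": seed, "lambda": lam, **shared},
    )
    return sample


# --------------------------------------------------------------------------
# structured-text configuration
# --------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "model" not in cfg:
        raise ValueError("config must be a mapping with at least a 'model' key")
    return cfg


def sample_from_config(cfg: Mapping) -> PairedSample:
    """Sample according to a config mapping.

    Keys: ``model``, ``params`` (shared), ``psi``, ``b``, ``seed``,
    ``nuisance`` (rule mapping or scalar/list).
    """
    model = make_model(cfg["model"], cfg.get("params"))
    psi = cfg.get("psi", 1.0)
    if isinstance(psi, list):
        psi = tuple(psi)
    return sample_blocks(
        model,
        int(cfg.get("b", 100)),
        cfg.get("nuisance", 1.0),
        psi,
        int(cfg.get("seed", 0)),
        shared=cfg.get("params"),
    )
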