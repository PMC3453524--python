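"""Gibbs samplers for polygenic, genomic-mixture and combined models.

Three model classes share one update cycle:

* ``polygenic``:  y = mu + X1 b + X2 c + Z u + e,  u ~ N(0, A sigma2_u)
* ``genomic``:    y = mu + X1 b + X2 c + Q(a o s) + e, with per-marker base
  effects a ~ N(0, 1) and scaling factors s carrying a two-component
  mixture prior: N(0, sigma2_g0) with probability pi0 (markers with
  essentially no effect; sigma2_g0 is fixed at 1% of the phenotypic
  variance divided by the marker count) and half-normal TN>0(0, sigma2_g1)
  with probability pi1 (markers with a substantial effect).  pi1 = 1
  recovers the non-mixture model where every scaling factor is half-normal.
* ``combined``: both genetic terms at once; the polygenic term absorbs
  genetic variation the markers cannot capture.

Variance components get scaled-inverse-chi-square full conditionals with a
flat prior on the variance (nu = -2, zero scale), the standard choice in
animal-breeding Gibbs samplers; sigma2_g0 is never sampled.  The mixture
indicator and scaling factor update jointly per marker with s integrated
analytically out of the component odds (the substantial component's
marginal likelihood carries the truncated-normal normalising factor
2*Phi(m/sqrt(v))), which mixes far better than an indicator update
conditional on the current s.
"""

from __future__ import annotations

import json as _json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .data_model import DesignEncoding, Pedigree, PhenotypeTable
from .relationship import relationship_inverse

ModelClass = Literal["polygenic", "genomic", "combined"]

#: mixture fractions used in the reference study; any value in (0, 1] works
STANDARD_PI1 = (1.0, 0.7, 0.4, 0.1, 0.075, 0.05, 0.025)


@dataclass
class ModelSpec:
    model: ModelClass = "genomic"
    pi1: float = 1.0
    include_cage: bool = True
    fixed_effects: Sequence[str] | None = None  # None = all in the table
    covariates: Sequence[str] | None = None
    sigma2_g0: float | None = None  # None = 1% of var(y) / n_markers

    def __post_init__(self):
        if self.model not in ("polygenic", "genomic", "combined"):
            raise ValueError(f"unknown model class {self.model!r}")
        if not (0.0 < self.pi1 <= 1.0):
            raise ValueError("pi1 must lie in (0, 1]")


@dataclass
class ChainSettings:
    iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorDraws:
    """Thinned MCMC samples plus everything needed for prediction."""

    model: str
    pi1: float
    sigma2_g0: float
    chain: ChainSettings
    mu: np.ndarray
    fixed: np.ndarray  # (S, pf)
    fixed_names: list[str]
    factor_levels: dict[str, list[str]]
    cage_effects: np.ndarray  # (S, ncage)
    cage_labels: list[str]
    sigma2_e: np.ndarray
    sigma2_c: np.ndarray
    sigma2_u: np.ndarray
    sigma2_g1: np.ndarray
    u: np.ndarray | None  # (S, nanim) in pedigree order
    pedigree_ids: tuple[str, ...] | None
    avec: np.ndarray | None  # (S, pcols): per-column total effect a*s
    s: np.ndarray | None  # (S, M)
    delta: np.ndarray | None  # (S, M)
    marker_ids: tuple[str, ...] | None
    encoding: DesignEncoding | None
    encoding_animal_ids: tuple[str, ...] | None
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_stored(self) -> int:
        return len(self.mu)

    def marker_effects(self) -> np.ndarray:
        """Posterior mean total effect per coded column (a*s)."""
        if self.avec is None:
            raise ValueError("model carries no marker effects")
        return self.avec.mean(axis=0)


def _fixed_design(table: PhenotypeTable, spec: ModelSpec, rows: np.ndarray):
    """Dummy-coded (drop-first) fixed factors plus covariates.

    Returns the design over the given rows, column names, and the factor
    levels of the *training* data so validation rows can be checked later.
    """
    fixed = spec.fixed_effects if spec.fixed_effects is not None else table.fixed_effects
    covs = spec.covariates if spec.covariates is not None else table.covariates
    cols, names = [], []
    levels: dict[str, list[str]] = {}
    df = table.data.iloc[rows]
    for f in fixed:
        lv = sorted(df[f].astype(str).unique())
        levels[f] = lv
        for l in lv[1:]:
            cols.append((df[f].astype(str) == l).to_numpy(dtype=np.float64))
            names.append(f"{f}[{l}]")
    for cvar in covs:
        cols.append(df[cvar].to_numpy(dtype=np.float64))
        names.append(cvar)
    X = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    return X, names, levels


def fit(
    spec: ModelSpec,
    phenotypes: PhenotypeTable,
    encoding: DesignEncoding | None = None,
    pedigree: Pedigree | None = None,
    chain: ChainSettings | None = None,
    *,
    encoding_animal_ids: Sequence[str] | None = None,
    fix_variances: dict[str, float] | None = None,
    freeze_delta: bool = False,
    freeze_s: float | None = None,
    likelihood: bool = True,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return thinned posterior draws.

    Animals with a missing trait value contribute no residual term but keep
    their polygenic value (linked through the pedigree) and genomic value
    (from their genotypes) — that is how validation animals are predicted.

    The keyword-only arguments exist for verification runs: fixing variance
    components at known values, freezing the mixture indicators at 1,
    freezing every scaling factor at a constant (which reduces the marker
    layer to ridge regression), or disabling the likelihood so the chain
    reproduces its own prior.
    """
    chain = chain or ChainSettings()
    use_genomic = spec.model in ("genomic", "combined")
    use_poly = spec.model in ("polygenic", "combined")
    if use_genomic and encoding is None:
        raise ValueError(f"model {spec.model!r} requires a marker DesignEncoding")
    if use_poly and pedigree is None:
        raise ValueError(f"model {spec.model!r} requires a Pedigree")

    obs = phenotypes.observed
    rows = np.flatnonzero(obs)
    if rows.size < 10:
        raise ValueError("need at least 10 observed phenotypes")
    y = phenotypes.data["value"].to_numpy(dtype=np.float64)[rows]
    animals = [phenotypes.animal_ids[i] for i in rows]

    Xf, fixed_names, factor_levels = _fixed_design(phenotypes, spec, rows)
    xtx_f = (Xf**2).sum(axis=0)
    if np.any(xtx_f <= 0):
        k = int(np.flatnonzero(xtx_f <= 0)[0])
        raise ValueError(f"fixed-effect column {fixed_names[k]!r} is constant zero")

    # cage incidence (CSR over observed rows)
    if spec.include_cage:
        cages = phenotypes.data["cage"].iloc[rows].astype(str)
        cage_codes, cage_labels = pd.factorize(cages)
        order = np.argsort(cage_codes, kind="stable")
        counts = np.bincount(cage_codes, minlength=len(cage_labels))
        cage_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        cage_rows = order.astype(np.int64)
        cage_labels = list(cage_labels)
    else:
        cage_ptr = np.zeros(1, dtype=np.int64)
        cage_rows = np.zeros(0, dtype=np.int64)
        cage_labels = []

    # polygenic structures
    if use_poly:
        ainv = relationship_inverse(pedigree).tocsr()
        ped_index = pedigree.index_of(animals)
        order = np.argsort(ped_index, kind="stable")
        counts = np.bincount(ped_index, minlength=len(pedigree))
        anim_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        anim_rows = order.astype(np.int64)
        ai_indptr = ainv.indptr.astype(np.int64)
        ai_indices = ainv.indices.astype(np.int64)
        ai_data = ainv.data.astype(np.float64)
        pedigree_ids = pedigree.ids
    else:
        anim_ptr = np.zeros(1, dtype=np.int64)
        anim_rows = np.zeros(0, dtype=np.int64)
        ai_indptr = np.zeros(1, dtype=np.int64)
        ai_indices = np.zeros(0, dtype=np.int64)
        ai_data = np.zeros(0, dtype=np.float64)
        pedigree_ids = None

    # marker design restricted to observed rows
    if use_genomic:
        enc_ids = tuple(encoding_animal_ids) if encoding_animal_ids else None
        if enc_ids is not None:
            lookup = {a: i for i, a in enumerate(enc_ids)}
            enc_rows = np.array([lookup[a] for a in animals])
        else:
            if encoding.matrix.shape[0] != len(phenotypes.animal_ids):
                raise ValueError(
                    "encoding rows do not match phenotype table; pass "
                    "encoding_animal_ids for the encoding's animal order"
                )
            enc_ids = phenotypes.animal_ids
            enc_rows = rows
        # centre every coded column: uncentred per-allele columns carry a
        # constant component (ref + alt = 2) that is confounded with mu and
        # lets s drift unboundedly under the flat sigma2_g1 prior
        cmat = encoding.matrix - encoding.matrix.mean(axis=0)
        encoding = DesignEncoding(
            encoding.mode, cmat, encoding.col_marker, encoding.marker_start
        )
        QT = np.ascontiguousarray(cmat[enc_rows].T)
        qss = (QT**2).sum(axis=1)
        marker_start = encoding.marker_start.astype(np.int64)
        n_markers = encoding.n_markers
    else:
        QT = np.zeros((0, rows.size))
        qss = np.zeros(0)
        marker_start = np.zeros(1, dtype=np.int64)
        enc_ids = None
        n_markers = 0

    var_y = float(np.var(y))
    sigma2_g0 = spec.sigma2_g0
    if sigma2_g0 is None:
        sigma2_g0 = 0.01 * var_y / max(n_markers, 1)

    fv = fix_variances or {}
    ve0 = fv.get("sigma2_e", 0.5 * var_y)
    vc0 = fv.get("sigma2_c", 0.1 * var_y)
    vu0 = fv.get("sigma2_u", 0.3 * var_y)
    vg10 = fv.get("sigma2_g1", max(var_y / max(n_markers * spec.pi1, 1.0), 1e-8))

    out = _kernels.run_chain(
        y,
        np.ascontiguousarray(Xf), xtx_f,
        cage_ptr, cage_rows,
        anim_ptr, anim_rows,
        ai_indptr, ai_indices, ai_data,
        QT, qss, marker_start,
        use_genomic, use_poly, spec.include_cage and len(cage_labels) > 0, likelihood,
        float(spec.pi1), float(sigma2_g0),
        float(ve0), float(vc0), float(vu0), float(vg10),
        "sigma2_e" not in fv, "sigma2_c" not in fv,
        "sigma2_u" not in fv, "sigma2_g1" not in fv,
        bool(freeze_delta), float(freeze_s if freeze_s is not None else 0.0),
        freeze_s is not None,
        int(chain.iterations), int(chain.burn_in), int(chain.thinning),
        int(chain.seed) & 0x7FFFFFFF,
    )
    (mu_s, bfix_s, c_s, u_s, avec_s, s_s, delta_s,
     ve_s, vc_s, vu_s, vg1_s, n_empty) = out

    if not np.all(np.isfinite(mu_s)):
        bad = int(np.flatnonzero(~np.isfinite(mu_s))[0])
        raise FloatingPointError(
            f"non-finite sampler state at stored draw {bad}; check input scaling"
        )
    warn_list = []
    post = chain.iterations - chain.burn_in
    if use_genomic and spec.pi1 > 0 and n_empty > 0.5 * post:
        msg = (
            f"substantial component empty in {n_empty}/{post} post-burn-in "
            "iterations; mixture may be degenerate"
        )
        warn_list.append(msg)
        warnings.warn(msg)

    mixture = use_genomic and spec.pi1 < 1.0
    return PosteriorDraws(
        model=spec.model,
        pi1=spec.pi1,
        sigma2_g0=sigma2_g0,
        chain=chain,
        mu=mu_s,
        fixed=bfix_s,
        fixed_names=fixed_names,
        factor_levels=factor_levels,
        cage_effects=c_s,
        cage_labels=cage_labels,
        sigma2_e=ve_s,
        sigma2_c=vc_s if spec.include_cage and cage_labels else np.zeros_like(ve_s),
        sigma2_u=vu_s if use_poly else np.zeros_like(ve_s),
        sigma2_g1=vg1_s if use_genomic else np.zeros_like(ve_s),
        u=u_s if use_poly else None,
        pedigree_ids=pedigree_ids,
        avec=avec_s if use_genomic else None,
        s=s_s if use_genomic else None,
        delta=delta_s if mixture or use_genomic else None,
        marker_ids=None,
        encoding=encoding if use_genomic else None,
        encoding_animal_ids=enc_ids,
        warnings_=warn_list,
    )


def marker_inclusion_probability(draws: PosteriorDraws) -> np.ndarray:
    """Posterior inclusion probability per marker, p1_hat = mean(delta).

    Clamped to [1/(2S), 1 - 1/(2S)] so downstream odds ratios stay finite
    even when a marker is in (or out of) the substantial component in every
    stored sample.
    """
    if draws.delta is None or draws.pi1 >= 1.0:
        raise ValueError(
            "inclusion probabilities require a mixture-model fit (pi1 < 1)"
        )
    S = draws.n_stored
    if S == 0:
        raise ValueError("no stored samples")
    p = draws.delta.mean(axis=0)
    half = 1.0 / (2.0 * S)
    return np.clip(p, half, 1.0 - half)


def genetic_values(
    draws: PosteriorDraws, which: Literal["polygenic", "genomic", "total"] = "total"
) -> pd.Series:
    """Posterior-mean genetic value per animal.

    ``polygenic`` returns the pedigree term u (all pedigree animals),
    ``genomic`` the marker term g = Q (a o s) (all genotyped animals),
    ``total`` their sum over the animals common to both (or whichever
    component the model has).
    """
    have_u = draws.u is not None
    have_g = draws.avec is not None
    if which == "polygenic" or (which == "total" and have_u and not have_g):
        if not have_u:
            raise ValueError(f"model {draws.model!r} has no polygenic component")
        return pd.Series(draws.u.mean(axis=0), index=list(draws.pedigree_ids))
    if which == "genomic" or (which == "total" and have_g and not have_u):
        if not have_g:
            raise ValueError(f"model {draws.model!r} has no genomic component")
        g = draws.encoding.matrix @ draws.avec.mean(axis=0)
        return pd.Series(g, index=list(draws.encoding_animal_ids))
    # total for the combined model
    upart = pd.Series(draws.u.mean(axis=0), index=list(draws.pedigree_ids))
    gpart = pd.Series(
        draws.encoding.matrix @ draws.avec.mean(axis=0),
        index=list(draws.encoding_animal_ids),
    )
    common = gpart.index
    return upart.reindex(common).fillna(0.0) + gpart


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist posterior draws to one HDF5 container.

    Layout: every array field is a dataset under the root group; scalar
    metadata (model class, pi1, sigma2_g0, chain settings) and id lists
    are stored as attributes / string datasets. The marker encoding matrix
    travels along so predictions can be recomputed after loading.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["model"] = draws.model
        f.attrs["pi1"] = draws.pi1
        f.attrs["sigma2_g0"] = draws.sigma2_g0
        f.attrs["chain"] = [draws.chain.iterations, draws.chain.burn_in,
                            draws.chain.thinning, draws.chain.seed]
        f.attrs["warnings"] = "\n".join(draws.warnings_)
        for name in ("mu", "fixed", "cage_effects", "sigma2_e", "sigma2_c",
                     "sigma2_u", "sigma2_g1", "u", "avec", "s", "delta"):
            arr = getattr(draws, name)
            if arr is not None:
                f.create_dataset(name, data=arr)
        str_dt = h5py.string_dtype()
        f.create_dataset("fixed_names", data=draws.fixed_names, dtype=str_dt)
        f.create_dataset("cage_labels", data=draws.cage_labels, dtype=str_dt)
        f.attrs["factor_levels"] = _json.dumps(draws.factor_levels)
        if draws.pedigree_ids is not None:
            f.create_dataset("pedigree_ids", data=list(draws.pedigree_ids),
                             dtype=str_dt)
        if draws.encoding is not None:
            f.create_dataset("encoding_matrix", data=draws.encoding.matrix)
            f.create_dataset("encoding_col_marker", data=draws.encoding.col_marker)
            f.create_dataset("encoding_marker_start",
                             data=draws.encoding.marker_start)
            f.attrs["encoding_mode"] = draws.encoding.mode
            f.create_dataset("encoding_animal_ids",
                             data=list(draws.encoding_animal_ids), dtype=str_dt)


def load_draws(path) -> PosteriorDraws:
    """Inverse of :func:`save_draws`."""
    import h5py

    with h5py.File(path, "r") as f:
        def get(name):
            return f[name][...] if name in f else None

        def strings(name):
            return [s.decode() if isinstance(s, bytes) else s for s in f[name][...]]

        it, burn, thin, seed = (int(x) for x in f.attrs["chain"])
        encoding = None
        enc_ids = None
        if "encoding_matrix" in f:
            encoding = DesignEncoding(
                str(f.attrs["encoding_mode"]), f["encoding_matrix"][...],
                f["encoding_col_marker"][...], f["encoding_marker_start"][...],
            )
            enc_ids = tuple(strings("encoding_animal_ids"))
        ped_ids = tuple(strings("pedigree_ids")) if "pedigree_ids" in f else None
        warn_text = str(f.attrs.get("warnings", ""))
        return PosteriorDraws(
            model=str(f.attrs["model"]),
            pi1=float(f.attrs["pi1"]),
            sigma2_g0=float(f.attrs["sigma2_g0"]),
            chain=ChainSettings(it, burn, thin, seed),
            mu=get("mu"),
            fixed=get("fixed"),
            fixed_names=strings("fixed_names"),
            factor_levels=_json.loads(str(f.attrs["factor_levels"])),
            cage_effects=get("cage_effects"),
            cage_labels=strings("cage_labels"),
            sigma2_e=get("sigma2_e"),
            sigma2_c=get("sigma2_c"),
            sigma2_u=get("sigma2_u"),
            sigma2_g1=get("sigma2_g1"),
            u=get("u"),
            pedigree_ids=ped_ids,
            avec=get("avec"),
            s=get("s"),
            delta=get("delta"),
            marker_ids=None,
            encoding=encoding,
            encoding_animal_ids=enc_ids,
            warnings_=[w for w in warn_text.split("\n") if w],
        )
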