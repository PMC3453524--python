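"""Posterior variance components, genomic variance and heritabilities.

The genomic variance sigma2_a of one posterior sample is the empirical
variance across animals of the genomic values g = Q beta.  Written out,
this equals the sum of per-marker contributions beta_j^2 var(q_j) plus
every pairwise covariance 2 beta_j beta_k cov(q_j, q_k) induced by linkage
disequilibrium, with the allele frequencies entering through the column
(co)variances — so LD between markers is fully accounted for.

The phenotypic variance of a sample is assembled from that sample's
components (sigma2_a + sigma2_u + sigma2_c + sigma2_e, absent components
contributing zero), which keeps every heritability draw inside [0, 1] by
construction.  Intervals are central 95% posterior quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DesignEncoding
from .sampler import PosteriorDraws


@dataclass(frozen=True)
class VarianceReport:
    """Posterior mean and central 95% interval per reported quantity."""

    table: pd.DataFrame  # index: component, columns: mean, lower, upper
    draws: pd.DataFrame  # per-sample component values

    def __str__(self) -> str:
        rows = []
        for name, r in self.table.iterrows():
            rows.append(f"{name:>8}: {r['mean']:8.3f}  [{r['lower']:.3f}, {r['upper']:.3f}]")
        return "\n".join(rows)


def genomic_variance_draw(
    marker_effects: np.ndarray, encoding: DesignEncoding
) -> float:
    """Genomic variance of one sample: var over animals of Q beta."""
    beta = np.asarray(marker_effects, dtype=np.float64)
    if beta.shape[0] != encoding.matrix.shape[1]:
        raise ValueError(
            f"effect vector length {beta.shape[0]} does not match "
            f"{encoding.matrix.shape[1]} encoded columns"
        )
    g = encoding.matrix @ beta
    return float(g.var())


def summarize(
    draws: PosteriorDraws, encoding: DesignEncoding | None = None
) -> VarianceReport:
    """Reduce posterior draws to the standard variance-component report."""
    S = draws.n_stored
    if S == 0:
        raise ValueError("no stored samples to summarise")
    has_genomic = draws.avec is not None
    has_poly = draws.u is not None
    if has_genomic:
        enc = encoding if encoding is not None else draws.encoding
        if enc is None:
            raise ValueError("genomic model requires the marker encoding")
        g_draws = enc.matrix @ draws.avec.T  # animals x S
        sigma2_a = g_draws.var(axis=0)
    else:
        sigma2_a = np.zeros(S)
    sigma2_u = draws.sigma2_u if has_poly else np.zeros(S)
    sigma2_c = draws.sigma2_c
    sigma2_e = draws.sigma2_e
    sigma2_p = sigma2_a + sigma2_u + sigma2_c + sigma2_e

    per_sample = {
        "sigma2_a": sigma2_a,
        "sigma2_u": sigma2_u,
        "sigma2_c": sigma2_c,
        "sigma2_e": sigma2_e,
        "sigma2_p": sigma2_p,
        "h2_u": sigma2_u / sigma2_p,
        "h2_a": sigma2_a / sigma2_p,
    }
    if not has_genomic:
        per_sample.pop("h2_a")
        per_sample.pop("sigma2_a")
    if not has_poly:
        per_sample.pop("h2_u")
        per_sample.pop("sigma2_u")

    sample_df = pd.DataFrame(per_sample)
    rows = {}
    for name, v in per_sample.items():
        rows[name] = {
            "mean": float(np.mean(v)),
            "lower": float(np.quantile(v, 0.025)),
            "upper": float(np.quantile(v, 0.975)),
        }
    table = pd.DataFrame(rows).T[["mean", "lower", "upper"]]
    return VarianceReport(table=table, draws=sample_df)


def report_to_csv(report: VarianceReport, path, model_label: str = "") -> None:
    out = report.table.copy()
    if model_label:
        out.insert(0, "model", model_label)
    out.to_csv(path, index_label="component")
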