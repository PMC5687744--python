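"""Application path for real abundance tables.

Raw OTU-by-time tables are filtered (keep taxa with at least a minimum
fraction of nonzero measurements), standardized per taxon to mean zero and
unit sample standard deviation (so a uniform L1 penalty treats abundant and
rare taxa comparably), fitted with the row-based ERM, and summarized as
one-step-ahead predictions with per-taxon R^2 and a signed directed edge
list. With standardized, unreplicated data the measurement noise variance is
not jointly identifiable with the system noise, so it is held fixed (at the
default 0.1, i.e. ten percent of the unit variance of a standardized series)
and only the system noise is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kalman import kalman_filter
from .ssm import ObservationSeries

__all__ = [
    "AbundanceTable",
    "PredictionReport",
    "read_abundance",
    "write_abundance",
    "filter_otus",
    "standardize",
    "one_step_predict",
    "export_network",
    "import_network",
]


@dataclass
class AbundanceTable:
    """Raw nonnegative abundances: rows = OTUs, columns = ordered time points."""

    values: np.ndarray  # (p_raw, T)
    otu_names: list[str]
    time_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("abundances must be nonnegative")
        if len(self.otu_names) != len(set(self.otu_names)):
            raise ValueError("duplicate OTU names")
        if self.values.shape != (len(self.otu_names), len(self.time_labels)):
            raise ValueError("values shape does not match labels")


@dataclass
class PredictionReport:
    y_pred: np.ndarray  # (T-1, p), predictions for t = 2..T
    r2: np.ndarray  # (p,)
    residuals: np.ndarray  # (T-1, p)
    names: list[str]


def read_abundance(path, format: str = "tsv") -> AbundanceTable:
    """Parse a delimited table: first column OTU names, then time points."""
    sep = {"tsv": "\t", "csv": ","}[format]
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.any(np.isnan(values)):
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric cell at OTU {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return AbundanceTable(
        values=values,
        otu_names=[str(n) for n in df.index],
        time_labels=[str(c) for c in df.columns],
    )


def write_abundance(table: AbundanceTable, path, format: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[format]
    pd.DataFrame(
        table.values, index=table.otu_names, columns=table.time_labels
    ).to_csv(path, sep=sep)


def filter_otus(table: AbundanceTable, min_nonzero_frac: float = 0.3) -> AbundanceTable:
    """Keep OTU i iff at least ``min_nonzero_frac`` of its measurements are > 0."""
    if not 0.0 < min_nonzero_frac <= 1.0:
        raise ValueError("min_nonzero_frac must be in (0, 1]")
    T = table.values.shape[1]
    frac = (table.values > 0).sum(axis=1) / T
    keep = frac >= min_nonzero_frac  # "at least" is inclusive
    if not np.any(keep):
        raise ValueError(
            "no OTUs pass the nonzero-fraction filter; lower min_nonzero_frac"
        )
    return AbundanceTable(
        values=table.values[keep],
        otu_names=[n for n, k in zip(table.otu_names, keep) if k],
        time_labels=list(table.time_labels),
    )


def standardize(table: AbundanceTable) -> ObservationSeries:
    """Per-OTU centering/scaling: Y_ij = (Y~_ij - mean_i) / sd_i (sample sd)."""
    V = table.values
    sd = V.std(axis=1, ddof=1)
    zero_sd = np.flatnonzero(sd == 0)
    if zero_sd.size:
        raise ValueError(
            f"OTU {table.otu_names[zero_sd[0]]!r} is constant over time; "
            "filter it before standardizing"
        )
    Z = (V - V.mean(axis=1, keepdims=True)) / sd[:, None]
    return ObservationSeries(Y=Z.T, names=list(table.otu_names))


def one_step_predict(fit, Y: ObservationSeries) -> PredictionReport:
    """One-step-ahead predictions y-hat_t = A x_{t-1}^{t-1}, t = 2..T.

    Filtered (causal) lagged states come from a filter pass at the fitted
    parameters. R^2 per taxon is computed over t = 2..T against the mean of
    the same window. ``fit`` may be a FitResult or a fitted ERMNetwork.
    """
    params = fit.params_ if hasattr(fit, "params_") else fit.params
    if params.p != Y.p:
        raise ValueError("fitted dimension does not match data")
    fr = kalman_filter(params, Y)
    y_pred = fr.filt_mean[:-1] @ params.A.T
    y_obs = Y.Y[1:]
    resid = y_obs - y_pred
    centered = y_obs - y_obs.mean(axis=0, keepdims=True)
    denom = (centered**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - (resid**2).sum(axis=0) / denom
    return PredictionReport(y_pred=y_pred, r2=r2, residuals=resid, names=Y.names)


def export_network(
    A_hat: np.ndarray, names: list[str], path, graphml_path=None
) -> pd.DataFrame:
    """Write the directed edge list (target, source, weight, sign) as TSV.

    Edge orientation: a_ij (row i, column j) is the effect of source j on
    target i. Edges are sorted by decreasing |weight|; a summary comment line
    records the nonzero count and density. Optionally also writes GraphML.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    p = A_hat.shape[0]
    if len(names) != p:
        raise ValueError("names length must match matrix dimension")
    rows, cols = np.nonzero(A_hat)
    weights = A_hat[rows, cols]
    order = np.argsort(-np.abs(weights))
    df = pd.DataFrame(
        {
            "target": [names[i] for i in rows[order]],
            "source": [names[j] for j in cols[order]],
            "weight": weights[order],
            "sign": ["positive" if w > 0 else "negative" for w in weights[order]],
        }
    )
    density = 100.0 * len(df) / (p * p)
    with open(path, "w") as fh:
        fh.write(f"# nonzero edges: {len(df)} of {p * p} ({density:.1f}%)\n")
        df.to_csv(fh, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(names)
        for _, r in df.iterrows():
            g.add_edge(r["source"], r["target"], weight=float(r["weight"]))
        nx.write_graphml(g, graphml_path)
    return df


def import_network(path, names: list[str]) -> np.ndarray:
    """Reconstruct the transition matrix from an exported edge list."""
    df = pd.read_csv(path, sep="\t", comment="#")
    index = {n: i for i, n in enumerate(names)}
    A = np.zeros((len(names), len(names)))
    for _, r in df.iterrows():
        A[index[str(r["target"])], index[str(r["source"])]] = float(r["weight"])
    return A
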