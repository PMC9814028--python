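"""Reading and writing the package's delimited-text formats.

Everything is plain text: disease-mapping data as a delimited table with
``area_id``, ``y``, ``E`` and optional covariate columns; MCMC chains as
long/tidy tables (chain, iter, quantity, area, value); summaries and
manifests as CSV/JSON; matrices as dense delimited text or sparse
coordinate triples.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .glmm import DiseaseMapData, PosteriorDraws

__all__ = [
    "read_data",
    "write_data",
    "draws_to_frame",
    "write_chains",
    "write_matrix",
    "write_coo",
    "write_manifest",
]


def read_data(path, standardize: bool = True) -> DiseaseMapData:
    """Read per-area counts from a delimited text file.

    The header must contain ``area_id``, ``y`` and ``E``; any further
    columns are treated as covariates.  Rows are sorted by ``area_id``
    (1-based).  Covariates are standardized to zero mean and unit
    variance unless ``standardize=False``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    for col in ("area_id", "y", "E"):
        if col not in df.columns:
            raise ValueError(f"data file {path} is missing required column {col!r}")
    df = df.sort_values("area_id").reset_index(drop=True)
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["area_id"].to_numpy(), expected):
        raise ValueError("area_id must be the consecutive integers 1..n")
    covars = [c for c in df.columns if c not in ("area_id", "y", "E")]
    X = None
    if covars:
        X = df[covars].to_numpy(dtype=float)
        if standardize:
            sd = X.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError("constant covariate column cannot be standardized")
            X = (X - X.mean(axis=0)) / sd
    return DiseaseMapData(y=df["y"].to_numpy(), E=df["E"].to_numpy(dtype=float), X=X)


def write_data(data: DiseaseMapData, path) -> None:
    df = pd.DataFrame(
        {"area_id": np.arange(1, data.n + 1), "y": data.y.astype(int), "E": data.E}
    )
    for j in range(data.p):
        df[f"x{j + 1}"] = data.X[:, j]
    df.to_csv(path, index=False)


def draws_to_frame(draws: PosteriorDraws, quantities=None) -> pd.DataFrame:
    """Long-format chain table: chain, iter, quantity, area, value.

    ``area`` is 1-based for vector quantities and empty for scalars.
    """
    if quantities is None:
        quantities = [
            nm
            for nm in ("mu", "beta", "c", "sigma", "sigma_s", "sigma_h",
                       "psi", "psi_s", "psi_h", "gamma")
            if getattr(draws, nm) is not None
        ]
    frames = []
    for name in quantities:
        arr = getattr(draws, name)
        C, T = arr.shape[:2]
        chain = np.repeat(np.arange(C), T)
        iters = np.tile(np.arange(T), C)
        if arr.ndim == 2:
            frames.append(
                pd.DataFrame(
                    {"chain": chain, "iter": iters, "quantity": name,
                     "area": pd.array([pd.NA] * (C * T), dtype="Int64"),
                     "value": arr.reshape(-1)}
                )
            )
        else:
            n = arr.shape[2]
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(chain, n),
                        "iter": np.repeat(iters, n),
                        "quantity": name,
                        "area": pd.array(np.tile(np.arange(1, n + 1), C * T), dtype="Int64"),
                        "value": arr.reshape(-1),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_chains(draws: PosteriorDraws, path, quantities=None) -> None:
    draws_to_frame(draws, quantities).to_csv(path, index=False)


def write_matrix(M: np.ndarray, path, fmt: str = "%.10g") -> None:
    """Dense matrix as whitespace-delimited text."""
    np.savetxt(path, np.asarray(M), fmt=fmt)


def write_coo(M, path) -> None:
    """Sparse coordinate triples ``i j value`` (1-based)."""
    import scipy.sparse as sp

    coo = sp.coo_matrix(M)
    with open(path, "w") as fh:
        fh.write("i j value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v:.10g}\n")


def write_manifest(path, **entries) -> None:
    """Reproducibility manifest: config, seed, package version."""
    from . import __version__

    payload = {"carfield_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
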