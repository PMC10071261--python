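"""Delimited-file input and report writers for the command-line interface."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import RegressionData
from .exceptions import DataValidationError
from .families import Family

__all__ = ["read_table", "write_fit_reports", "config_hash"]


def read_table(
    path,
    response: str,
    covariates,
    family: Family,
    offset_col: str | None = None,
    raw_population: bool = False,
    labels_col: str | None = None,
) -> RegressionData:
    """Read a CSV/TSV file with header into validated RegressionData.

    ``offset_col`` holds the offset on the log scale unless
    ``raw_population`` is set, in which case the column is a raw population
    count and its natural log is taken (an explicit flag — never a silent
    transform).  Errors are addressed by row and column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    covariates = list(covariates)
    needed = [response, *covariates]
    if offset_col:
        needed.append(offset_col)
    if labels_col:
        needed.append(labels_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")

    for col in needed:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.flatnonzero(df[col].isna() | bad)[0])
            raise DataValidationError(
                f"{path}: non-numeric or missing value in column {col!r}, row {row}"
            )

    y = df[response].astype(float).to_numpy()
    X = df[covariates].astype(float).to_numpy() if covariates else np.empty((len(df), 0))
    offset = None
    if offset_col:
        offset = df[offset_col].astype(float).to_numpy()
        if raw_population:
            if np.any(offset <= 0):
                row = int(np.flatnonzero(offset <= 0)[0])
                raise DataValidationError(
                    f"{path}: population must be positive (column {offset_col!r},"
                    f" row {row})"
                )
            offset = np.log(offset)
    labels = df[labels_col].astype(int).to_numpy() if labels_col else None

    data = RegressionData(y=y, X=X, offset=offset, true_labels=labels)
    try:
        data.validate_for(family)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: column {response!r}: {exc}") from exc
    return data


def config_hash(config: dict) -> str:
    """Short stable hash of a run configuration, for report provenance."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_fit_reports(outdir: Path, k: int, results, provenance: dict) -> list[Path]:
    """Write params_k{k}.json, posteriors_k{k}.csv, deviance_k{k}.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    params = results.params
    bse = results.bse()
    payload = {
        "k": k,
        "family": results.model.family.name,
        "pi": params.pi.tolist(),
        "beta": params.beta.tolist(),
        "beta_se": bse.tolist(),
        "phi": params.phi.tolist(),
        "soft_sizes": results.soft_sizes.tolist(),
        "loglik": results.llf,
        "converged": bool(results.converged),
        "bic": results.bic,
        "icl": results.icl,
        **provenance,
    }
    p = outdir / f"params_k{k}.json"
    p.write_text(json.dumps(payload, indent=2))
    written.append(p)

    post = pd.DataFrame(
        results.posteriors, columns=[f"z_{j+1}" for j in range(results.k)]
    )
    post["map_label"] = results.map_labels
    p = outdir / f"posteriors_k{k}.csv"
    post.to_csv(p, index=False, float_format="%.17g")
    written.append(p)

    dec = results.deviance().to_dict()
    dec.update(provenance)
    p = outdir / f"deviance_k{k}.json"
    p.write_text(json.dumps(dec, indent=2))
    written.append(p)
    return written
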