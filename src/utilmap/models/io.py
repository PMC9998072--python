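"""Lossless coefficient-CSV serialization of fit results.

One row per parameter (part, component, name, estimate, se) preceded by
``#``-prefixed header lines carrying the family, fit metadata and model
options.  The file round-trips to a :class:`MappingResults` that predicts
identically to the in-memory fit; it is the input of the ``utilmap predict``
calculator.
"""

from __future__ import annotations

import io
import json

import numpy as np
import pandas as pd

from .base import MappingResults, param_index

__all__ = ["results_to_csv", "results_from_csv", "FORMAT_VERSION"]

FORMAT_VERSION = "utilmap-coefficients v1"


def _fmt(x: float) -> str:
    if isinstance(x, float) and (np.isnan(x) or np.isinf(x)):
        return json.dumps(x if np.isnan(x) else ("inf" if x > 0 else "-inf"))
    return repr(float(x))


def _parse(s: str) -> float:
    s = s.strip()
    if s in ('"inf"', "inf"):
        return np.inf
    if s in ('"-inf"', "-inf"):
        return -np.inf
    if s in ("NaN", "nan", '"nan"', ""):
        return np.nan
    return float(s)


def results_to_csv(res: MappingResults, path) -> None:
    lines = [f"# {FORMAT_VERSION}"]
    lines.append(f"# family={res.family}")
    lines.append(f"# nobs={res.nobs}")
    lines.append(f"# llf={_fmt(res.llf)}")
    lines.append(f"# k_params={res.k_params}")
    lines.append(f"# converged={res.converged}")
    lines.append(f"# n_starts_used={res.n_starts_used}")
    lines.append("# exog_names=" + ",".join(res.exog_names))
    for key, value in sorted(res.options.items()):
        lines.append(f"# option:{key}={json.dumps(value)}")
    lines.append("part,component,name,estimate,se")
    for (part, comp, name), est in res.params.items():
        se = res.bse.loc[(part, comp, name)]
        lines.append(f"{part},{comp},{name},{_fmt(est)},{_fmt(se)}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def results_from_csv(path) -> MappingResults:
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines or FORMAT_VERSION not in lines[0]:
        raise ValueError(f"not a {FORMAT_VERSION} coefficient file")
    meta: dict[str, str] = {}
    options: dict = {}
    body_start = 0
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            key = key.strip()
            if key.startswith("option:"):
                options[key[len("option:"):]] = json.loads(value)
            else:
                meta[key] = value
        else:
            body_start = i
            break
    body = pd.read_csv(
        io.StringIO("\n".join(lines[body_start:])),
        converters={"estimate": _parse, "se": _parse},
    )
    idx = param_index(
        [(r.part, int(r.component), str(r.name)) for r in body.itertuples()]
    )
    return MappingResults(
        family=meta["family"],
        params=pd.Series(body["estimate"].to_numpy(), index=idx),
        bse=pd.Series(body["se"].to_numpy(), index=idx),
        llf=_parse(meta["llf"]),
        k_params=int(meta["k_params"]),
        nobs=int(meta["nobs"]),
        exog_names=meta["exog_names"].split(","),
        converged=meta.get("converged", "True") == "True",
        n_starts_used=int(meta.get("n_starts_used", 1)),
        options=options,
    )
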