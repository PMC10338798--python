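"""Thin driver for JAGS through Rscript (rjags).

The model string, data and per-chain initial values (including RNG seeds,
which make runs bit-reproducible) are exchanged as JSON; posterior draws
come back as one Feather file per chain.
"""

from __future__ import annotations

import json
import re
import subprocess
import tempfile
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

_R_SCRIPT = r"""
suppressMessages({library(rjags); library(jsonlite); library(arrow)})
args <- commandArgs(trailingOnly = TRUE)
wd <- args[1]
spec <- fromJSON(file.path(wd, "run.json"), simplifyVector = TRUE)
data <- fromJSON(file.path(wd, "data.json"), simplifyVector = TRUE)
inits <- fromJSON(file.path(wd, "inits.json"), simplifyVector = FALSE)
inits <- lapply(inits, function(ch) {
  ch <- lapply(ch, function(v) if (is.list(v)) unlist(v) else v)
  ch
})
m <- jags.model(file.path(wd, "model.txt"), data = data, inits = inits,
                n.chains = spec$n_chains, n.adapt = spec$n_adapt,
                quiet = TRUE)
if (spec$n_update > 0) update(m, spec$n_update)
s <- coda.samples(m, variable.names = unlist(spec$monitors),
                  n.iter = spec$n_sample, thin = spec$thin)
for (i in seq_along(s)) {
  write_feather(as.data.frame(as.matrix(s[[i]])),
                file.path(wd, sprintf("chain%d.feather", i)))
}
cat("OK\n")
"""


class JagsError(RuntimeError):
    pass


def _jsonable(value):
    if isinstance(value, np.ndarray):
        out = value.tolist()
        return _nanify(out)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def _nanify(obj):
    if isinstance(obj, list):
        return [_nanify(x) for x in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_jags(
    model: str,
    data: dict,
    inits: list[dict],
    monitors: list[str],
    n_iter: int,
    n_burn: int,
    thin: int = 1,
    n_adapt: int = 1000,
    workdir=None,
) -> dict[str, np.ndarray]:
    """Run JAGS and return draws keyed by variable name.

    ``n_iter`` is the total per-chain length including ``n_burn`` discarded
    iterations (adaptation is extra).  Scalar variables come back with
    shape ``(chain, draw)``; indexed variables ``name[i]`` are assembled
    into ``(chain, draw, i)`` arrays (1-based JAGS indices mapped to 0).
    """
    if n_burn >= n_iter:
        raise ValueError("n_burn must be smaller than n_iter")
    spec = {
        "n_chains": len(inits),
        "n_adapt": n_adapt,
        "n_update": n_burn,
        "n_sample": n_iter - n_burn,
        "thin": thin,
        "monitors": list(monitors),
    }
    tmp_ctx = (
        tempfile.TemporaryDirectory()
        if workdir is None
        else _NullContext(Path(workdir))
    )
    with tmp_ctx as wd:
        wd = Path(wd)
        wd.mkdir(parents=True, exist_ok=True)
        (wd / "model.txt").write_text(model)
        (wd / "run.json").write_text(json.dumps(spec))
        (wd / "data.json").write_text(
            json.dumps({k: _jsonable(v) for k, v in data.items()})
        )
        (wd / "inits.json").write_text(
            json.dumps([{k: _jsonable(v) for k, v in ch.items()} for ch in inits])
        )
        (wd / "driver.R").write_text(_R_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(wd / "driver.R"), str(wd)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or "OK" not in proc.stdout:
            raise JagsError(
                f"JAGS run failed:\nstdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        chains = []
        for i in range(len(inits)):
            chains.append(pd.read_feather(wd / f"chain{i + 1}.feather"))
    return _collect(chains)


class _NullContext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


_INDEXED = re.compile(r"^(.*)\[(\d+)\]$")


def _collect(chains: list[pd.DataFrame]) -> dict[str, np.ndarray]:
    columns = list(chains[0].columns)
    scalars = []
    vectors = defaultdict(dict)
    for col in columns:
        m = _INDEXED.match(col)
        if m:
            vectors[m.group(1)][int(m.group(2))] = col
        else:
            scalars.append(col)
    out: dict[str, np.ndarray] = {}
    for name in scalars:
        out[name] = np.stack([c[name].to_numpy() for c in chains])
    for name, idx_map in vectors.items():
        idx = sorted(idx_map)
        cols = [idx_map[i] for i in idx]
        size = idx[-1]  # JAGS indices are 1-based; keep absolute positions
        arr = np.full((len(chains), len(chains[0]), size), np.nan)
        pos = np.array(idx) - 1
        for c, frame in enumerate(chains):
            arr[c][:, pos] = frame[cols].to_numpy()
        out[name] = arr
    return out
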