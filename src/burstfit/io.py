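"""Plain-text I/O: snapshot tables, run configuration, chains, provenance.

Snapshot format
---------------
Tab-separated with header ``time_min  ts_count  mrna_count  n_cells``; one
row per observed cell state per time point (per-cell rows with n_cells = 1
are accepted and aggregated).  Times are minutes relative to the stimulus;
the pre-stimulus sample has time_min = 0.

Configuration format
--------------------
YAML (a JSON file is valid YAML).  Schema::

    model:
      n_alleles: 2
      stimulus_params: [k1]
    parameters:        # scalar, or {U: pre, S: post} for stimulus parameters
      k1: {U: 0.01, S: 1.0}
      k0: 0.1
      mu0: 0.01
      mu1: 2.0
      delta: 0.05
    fixed: [delta]
    state_space: {M: 200}
    mcmc:              # all optional
      T: 10000
      seed: 0
      sigma: {k1: 1.0e-5, k0: 1.0e-5, mu0: 1.0e-5, mu1: 1.0e-3}

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .inference import Chain, default_sigma
from .likelihood import SnapshotDataset
from .model import ModelSpec, ParameterSet, StateSpace, build_two_state_model

__all__ = [
    "read_snapshots",
    "write_snapshots",
    "load_config",
    "write_chain",
    "read_chain",
    "provenance_record",
]

SNAPSHOT_COLUMNS = ["time_min", "ts_count", "mrna_count", "n_cells"]


def read_snapshots(path: str | Path) -> SnapshotDataset:
    """Load a snapshot TSV, aggregating per-cell rows into state counts."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SNAPSHOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("ts_count", "mrna_count", "n_cells"):
        bad = df.index[(df[col] < 0) | (df[col] != df[col].astype(int))]
        if len(bad):
            raise ValueError(
                f"{path}: column {col!r} must hold nonnegative integers "
                f"(first bad row: {int(bad[0]) + 2})"  # +2: header + 1-based
            )
    tables: dict[float, dict[tuple[int, int], int]] = defaultdict(lambda: defaultdict(int))
    for row in df.itertuples(index=False):
        tables[float(row.time_min)][(int(row.ts_count), int(row.mrna_count))] += int(row.n_cells)
    times = sorted(tables)
    return SnapshotDataset(
        time_points=tuple(times),
        counts=tuple(dict(tables[t]) for t in times),
        provenance={"source": str(path)},
    )


def write_snapshots(data: SnapshotDataset, path: str | Path) -> None:
    """Write a snapshot data set as the canonical aggregated TSV."""
    rows = []
    for t, table in zip(data.time_points, data.counts):
        for (ts, m) in sorted(table):
            rows.append({"time_min": t, "ts_count": ts, "mrna_count": m,
                         "n_cells": table[(ts, m)]})
    pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_distribution(P, path: str | Path) -> None:
    """Dump a model distribution as TSV (ts_count, mrna_count, probability)."""
    space = P.space
    rho1, m = space.states()
    pd.DataFrame(
        {"ts_count": rho1, "mrna_count": m, "probability": P.values}
    ).to_csv(path, sep="\t", index=False)


def _require_keys(section: dict, allowed: set[str], context: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse and validate a run configuration.

    Returns a dict with keys ``params`` (ParameterSet), ``space``
    (StateSpace), ``mcmc`` (dict of sampler settings), and ``raw``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    _require_keys(raw, {"model", "parameters", "fixed", "state_space", "mcmc"}, "config")

    model_sec = raw.get("model", {})
    _require_keys(model_sec, {"n_alleles", "stimulus_params"}, "config.model")
    n_alleles = int(model_sec.get("n_alleles", 2))
    stimulus = tuple(model_sec.get("stimulus_params", ()))
    base = build_two_state_model(n_alleles)
    model = ModelSpec(
        n_alleles=base.n_alleles,
        reactions=base.reactions,
        parameter_names=base.parameter_names,
        stimulus_params=stimulus,
        name="+".join(stimulus) + "_stim" if stimulus else "no_stim",
    )

    param_sec = raw.get("parameters", {})
    _require_keys(param_sec, set(model.parameter_names), "config.parameters")
    values_U, values_S = {}, {}
    for name in model.parameter_names:
        if name not in param_sec:
            raise ValueError(f"config.parameters missing {name!r}")
        entry = param_sec[name]
        if isinstance(entry, dict):
            _require_keys(entry, {"U", "S"}, f"config.parameters.{name}")
            if name not in stimulus:
                raise ValueError(
                    f"parameter {name!r} has U/S values but is not in stimulus_params"
                )
            values_U[name] = float(entry["U"])
            values_S[name] = float(entry["S"])
        else:
            values_U[name] = values_S[name] = float(entry)

    fixed = frozenset(raw.get("fixed", []))
    params = ParameterSet(model, values_U, values_S, fixed)

    space_sec = raw.get("state_space", {})
    _require_keys(space_sec, {"M"}, "config.state_space")
    M = int(space_sec.get("M", 500))
    space = StateSpace(M=M, p=model.p)

    mcmc_sec = dict(raw.get("mcmc", {}))
    _require_keys(mcmc_sec, {"T", "seed", "sigma"}, "config.mcmc")
    mcmc: dict[str, Any] = {
        "T": int(mcmc_sec.get("T", 100_000)),
        "seed": int(mcmc_sec.get("seed", 0)),
    }
    if "sigma" in mcmc_sec:
        sig = mcmc_sec["sigma"]
        _require_keys(sig, set(model.parameter_names), "config.mcmc.sigma")
        diag = []
        for comp in params.free_names:
            base_name = comp[:-2] if comp.endswith(("_U", "_S")) else comp
            diag.append(float(sig.get(base_name, 1e-5)))
        mcmc["sigma"] = np.diag(diag)
    else:
        mcmc["sigma"] = default_sigma(params.free_names)
    return {"params": params, "space": space, "mcmc": mcmc, "raw": raw}


def write_chain(chain: Chain, prefix: str | Path) -> tuple[Path, Path]:
    """Persist a chain as ``<prefix>.tsv`` plus a JSON sidecar of metadata."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    chain.to_frame().to_csv(tsv, sep="\t", index=False)
    sidecar = prefix.with_suffix(".json")
    meta = {
        "seed": int(chain.seed),
        "free_names": list(chain.free_names),
        "sigma_diag": np.diag(chain.sigma).tolist(),
        "burn_in_index": int(chain.burn_in_index),
        "acceptance_rate": chain.acceptance_rate,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return tsv, sidecar


def read_chain(prefix: str | Path) -> Chain:
    """Load a chain written by :func:`write_chain` (no likelihood attached)."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    names = meta["free_names"]
    return Chain(
        thetas=df[names].to_numpy(),
        loglik=df["loglik"].to_numpy(),
        accepted=df["accepted"].to_numpy().astype(bool),
        free_names=tuple(names),
        sigma=np.diag(meta["sigma_diag"]),
        seed=meta["seed"],
        burn_in_index=meta["burn_in_index"],
    )


def provenance_record(config: dict[str, Any] | None, seed: int, extra: dict | None = None) -> dict:
    """A reproducibility stamp written next to every run output."""
    from . import __version__

    raw = config.get("raw") if config else None
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    rec = {
        "version": __version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    if extra:
        rec.update(extra)
    return rec
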