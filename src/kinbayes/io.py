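"""Readers and writers: long-format CSV datasets, YAML/JSON model, prior and
sampler configuration files, chain serialization, and run manifests.

The data format is a long CSV with columns ``isotopomer,time,replicate,
abundance`` on a complete grid; times are floating-point hours by convention
(the library itself is unit-agnostic).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import DataError, KinbayesError, ModelSpecError
from .model import KineticModelSpec, Reaction, TimeSeriesDataset
from .priors import BetaPrior
from .sampler import PosteriorChain, SamplerConfig
from .synthetic import make_exemplar_network

DATA_COLUMNS = ["isotopomer", "time", "replicate", "abundance"]


def load_dataset(path: str | Path) -> TimeSeriesDataset:
    """Read and validate a long-format CSV into a TimeSeriesDataset."""
    df = pd.read_csv(path)
    missing = [c for c in DATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    bad = df[~np.isfinite(df["abundance"]) | (df["abundance"] <= 0)]
    if not bad.empty:
        row = bad.index[0]
        raise DataError(
            f"{path}: non-positive or non-finite abundance at row {row} "
            f"(isotopomer={bad.iloc[0]['isotopomer']}, time={bad.iloc[0]['time']})"
        )
    dup = df.duplicated(subset=["isotopomer", "time", "replicate"])
    if dup.any():
        raise DataError(f"{path}: duplicate (isotopomer,time,replicate) key at row {dup.idxmax()}")
    isotopomers = list(pd.unique(df["isotopomer"]))
    times = np.sort(df["time"].unique())
    replicates = sorted(df["replicate"].unique())
    T, m, n = len(times), len(replicates), len(isotopomers)
    if len(df) != T * m * n:
        raise DataError(
            f"{path}: ragged grid — {len(df)} rows, expected {T}x{m}x{n} = {T * m * n}"
        )
    tidx = {t: a for a, t in enumerate(times)}
    jidx = {r: a for a, r in enumerate(replicates)}
    iidx = {s: a for a, s in enumerate(isotopomers)}
    y = np.full((T, m, n), np.nan)
    y[
        df["time"].map(tidx).to_numpy(),
        df["replicate"].map(jidx).to_numpy(),
        df["isotopomer"].map(iidx).to_numpy(),
    ] = df["abundance"].to_numpy()
    if np.isnan(y).any():
        raise DataError(f"{path}: incomplete grid — some (isotopomer,time,replicate) cells missing")
    return TimeSeriesDataset(times=times, abundances=y, isotopomers=isotopomers)


def save_dataset(data: TimeSeriesDataset, path: str | Path) -> None:
    """Write a TimeSeriesDataset to long-format CSV."""
    rows = []
    for t_i, t in enumerate(data.times):
        for j in range(data.m):
            for i, iso in enumerate(data.isotopomers):
                rows.append((iso, float(t), j + 1, data.abundances[t_i, j, i]))
    pd.DataFrame(rows, columns=DATA_COLUMNS).to_csv(path, index=False)


def _read_structured(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_model(path_or_name: str | Path) -> KineticModelSpec:
    """Load a kinetic model from YAML/JSON, or by exemplar name.

    Document schema: ``states`` (ordered name -> initial value mapping),
    ``reactions`` (list of {parameter, reactants, products}), optional
    ``observed`` (state-name list) and ``parameters`` (explicit order).
    """
    name = str(path_or_name)
    if not Path(name).exists():
        try:
            return make_exemplar_network(name)
        except ModelSpecError:
            raise ModelSpecError(f"{name!r} is neither a model file nor an exemplar name") from None
    doc = _read_structured(path_or_name)
    if isinstance(doc, dict) and "exemplar" in doc:
        return make_exemplar_network(doc["exemplar"])
    try:
        states = doc["states"]
        reactions = [
            Reaction(
                parameter=r["parameter"],
                reactants=tuple(r.get("reactants", [])),
                products=tuple(r.get("products", [])),
                name=r.get("name"),
            )
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError) as e:
        raise ModelSpecError(f"{path_or_name}: invalid model document ({e})") from e
    return KineticModelSpec.from_reactions(
        state_names=list(states),
        initial_state=[float(states[s]) for s in states],
        reactions=reactions,
        parameter_names=doc.get("parameters"),
        observed=doc.get("observed"),
    )


def load_prior(path: str | Path, parameter_names: list[str]) -> BetaPrior:
    """Load a truncated-normal prior from a YAML/JSON range file.

    Schema: ``parameters`` mapping each name to {mean?, sd?, lower, upper}.
    """
    doc = _read_structured(path)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise KinbayesError(f"{path}: prior file must contain a 'parameters' mapping")
    return BetaPrior.from_ranges(parameter_names, doc["parameters"])


def load_sampler_config(path: str | Path, seed: int | None = None) -> SamplerConfig:
    """Load sampler settings from YAML/JSON; ``seed`` overrides the file."""
    doc = _read_structured(path) or {}
    if seed is not None:
        doc["seed"] = seed
    if "C0" in doc and doc["C0"] is not None:
        doc["C0"] = np.asarray(doc["C0"], dtype=float)
    return SamplerConfig(**doc)


def save_chain(chain: PosteriorChain, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize a chain: columnar CSV of all draws plus a JSON sidecar.

    All iterations are stored (burn-in marked in the sidecar, no thinning)
    because credible values are tail-sensitive.
    """
    prefix = Path(prefix)
    cols = {f"beta.{p}": chain.beta_draws[:, j] for j, p in enumerate(chain.parameter_names)}
    cols.update(
        {f"sigma2.{s}": chain.sigma2_draws[:, i] for i, s in enumerate(chain.isotopomer_ids)}
    )
    cols["log_posterior"] = chain.log_posterior_trace
    csv_path = prefix.with_suffix(".csv")
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {
        "burn_in": chain.burn_in,
        "n_iter": chain.n_iter,
        "seed": chain.seed,
        "parameter_names": chain.parameter_names,
        "isotopomer_ids": chain.isotopomer_ids,
        "acceptance": {k: list(v) for k, v in chain.acceptance.items()},
        "acceptance_rates": chain.acceptance_rates(),
        "ode_failures": chain.ode_failures,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def load_chain(prefix: str | Path) -> PosteriorChain:
    """Read a chain serialized by :func:`save_chain`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    beta = df[[f"beta.{p}" for p in meta["parameter_names"]]].to_numpy()
    sigma2 = df[[f"sigma2.{s}" for s in meta["isotopomer_ids"]]].to_numpy()
    return PosteriorChain(
        beta_draws=beta,
        sigma2_draws=sigma2,
        log_posterior_trace=df["log_posterior"].to_numpy(),
        acceptance={k: tuple(v) for k, v in meta["acceptance"].items()},
        burn_in=int(meta["burn_in"]),
        parameter_names=list(meta["parameter_names"]),
        isotopomer_ids=list(meta["isotopomer_ids"]),
        seed=meta.get("seed"),
        ode_failures=int(meta.get("ode_failures", 0)),
    )


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = __version__
    started: str = ""
    finished: str = ""

    @staticmethod
    def _digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = self._digest(path)

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def write(self, path: str | Path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
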