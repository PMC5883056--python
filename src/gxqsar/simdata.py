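"""Synthetic data generation.

The generators emulate the statistical structure the pipeline assumes: a
descriptor/activity table with a planted sparse linear relationship plus
Gaussian noise (standing in for the curated cell-line training sets, whose
descriptor values came from proprietary software), and a screening library
with constructed pass/fail ground truth under a frozen model. A packaged set
of hand-checkable fixture molecules carries brute-force oracle descriptor
values computed by independent scripts.

All randomness is seeded explicitly; no global random state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import ActivityTable
from .errors import ConfigError
from .qsar import LinearQSARModel, predict
from .screen import ScreeningRecord

#: Default descriptor sampling distributions, patterned on the frozen U251
#: model's inputs: small non-negative integer counts for the topological
#: pair descriptors and a continuous non-negative range for the E-state sum.
DEFAULT_DISTRIBUTIONS = {
    "T_T_N_4": ("int", 0, 10),
    "T_O_O_3": ("int", 0, 4),
    "SssssCE-index": ("uniform", 0.0, 3.0),
}


@dataclass
class SimConfig:
    """Configuration of the planted-signal table generator.

    ``true_beta`` maps descriptor names to their true coefficients; noise is
    Gaussian with sd ``noise_sd`` on the log10 µM activity scale. Descriptors
    without an entry in ``distributions`` default to uniform(0, 1); noise
    descriptors (named but absent from ``true_beta``) have coefficient 0.
    """

    n_compounds: int
    descriptor_names: list[str]
    true_beta: dict[str, float]
    intercept: float = 0.0
    noise_sd: float = 0.1
    distributions: dict[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        unknown = set(self.true_beta) - set(self.descriptor_names)
        if unknown:
            raise ConfigError(f"true_beta names not in descriptor_names: {sorted(unknown)}")
        k = len(self.descriptor_names)
        if self.n_compounds < k + 3:
            raise ConfigError(f"need n_compounds >= k + 3 (k={k})")


def _draw(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind, lo, hi = dist
    if hi < lo:
        raise ConfigError(f"impossible distribution bounds {dist}")
    if kind == "uniform":
        return rng.uniform(lo, hi, size=n)
    if kind == "int":
        return rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
    raise ConfigError(f"unknown distribution kind {kind!r}")


def simulate_descriptor_table(config: SimConfig) -> ActivityTable:
    """Draw a descriptor/activity table with a planted linear signal.

    activity = intercept + sum(beta * x) + Normal(0, noise_sd), deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    data = {}
    for name in config.descriptor_names:
        dist = config.distributions.get(name, ("uniform", 0.0, 1.0))
        data[name] = _draw(rng, dist, config.n_compounds)
    df = pd.DataFrame(data)
    y = np.full(config.n_compounds, config.intercept, dtype=float)
    for name, beta in config.true_beta.items():
        y += beta * df[name].to_numpy()
    y += rng.normal(0.0, config.noise_sd, size=config.n_compounds)
    df["log_ic50"] = y
    df.insert(0, "compound_id", [f"sim{i:04d}" for i in range(config.n_compounds)])
    return ActivityTable.from_dataframe(df, config.descriptor_names)


def planted_model3_config(
    n_compounds: int = 150,
    noise_sd: float = 0.1,
    n_noise_descriptors: int = 7,
    seed: int = 0,
) -> SimConfig:
    """The standard recovery scenario: the frozen U251 coefficients planted
    among uninformative noise descriptors."""
    from .qsar import published_model

    model = published_model("model3")
    noise_names = [f"noise{i}" for i in range(n_noise_descriptors)]
    return SimConfig(
        n_compounds=n_compounds,
        descriptor_names=list(model.descriptor_names) + noise_names,
        true_beta=dict(model.coefficients),
        intercept=model.intercept,
        noise_sd=noise_sd,
        distributions=dict(DEFAULT_DISTRIBUTIONS),
        seed=seed,
    )


def fixture_molecules() -> list[dict]:
    """The packaged hand-checkable molecule set.

    Each entry is ``{"name", "smiles", "descriptors"}`` where the descriptor
    values were precomputed by the independent brute-force oracle scripts in
    the test tree and frozen here; the live engine is tested against them.
    """
    text = resources.files("gxqsar.data").joinpath("fixture_molecules.json").read_text()
    return json.loads(text)


def simulate_screening_library(
    n: int,
    model: LinearQSARModel,
    pass_fraction: float,
    seed: int = 0,
    threshold_uM: float = 20.0,
    distributions: Optional[dict] = None,
    max_tries: int = 10_000,
) -> tuple[list[ScreeningRecord], dict[str, bool]]:
    """A descriptor-only library with known pass/fail ground truth.

    Each compound's pass label is drawn Bernoulli(pass_fraction); its
    descriptor vector is then rejection-sampled until the model prediction
    falls on the required side of the activity threshold (pass: IC50 <=
    threshold; fail: strictly greater). Returns (records, truth labels).
    """
    if not 0 <= pass_fraction <= 1:
        raise ConfigError("pass_fraction must be in [0, 1]")
    if distributions is None:
        distributions = {
            name: DEFAULT_DISTRIBUTIONS.get(name, ("uniform", 0.0, 1.0))
            for name in model.descriptor_names
        }
    rng = np.random.default_rng(seed)
    records: list[ScreeningRecord] = []
    truth: dict[str, bool] = {}
    for i in range(n):
        want_pass = bool(rng.random() < pass_fraction)
        for attempt in range(max_tries):
            vec = {
                name: float(_draw(rng, distributions[name], 1)[0])
                for name in model.descriptor_names
            }
            ic50 = predict(model, vec).ic50_uM
            if (ic50 <= threshold_uM) == want_pass:
                break
        else:
            raise ConfigError(
                f"could not sample a {'pass' if want_pass else 'fail'} vector under the "
                f"given distributions after {max_tries} tries; requested fraction infeasible"
            )
        cid = f"lib{i:05d}"
        records.append(ScreeningRecord(compound_id=cid, descriptors=vec))
        truth[cid] = want_pass
    return records, truth


def boundary_descriptor_vector(
    model: LinearQSARModel, threshold_uM: float = 20.0, free_name: Optional[str] = None
) -> dict[str, float]:
    """A descriptor vector predicting an IC50 as close to the threshold as
    floating point allows without exceeding it (searched over a few ulps
    around the algebraic solution), for exercising the strict "more than"
    exclusion boundary end to end."""
    free_name = free_name or model.descriptor_names[-1]
    others = {n: 0.0 for n in model.descriptor_names if n != free_name}
    coef = model.coefficients[free_name]
    if coef == 0:
        raise ConfigError(f"descriptor {free_name} has zero coefficient")
    x0 = (math.log10(threshold_uM) - model.intercept) / coef

    def key(x):
        ic50 = predict(model, {**others, free_name: x}).ic50_uM
        # only the passing side (<= threshold) qualifies; then minimize error
        return (ic50 > threshold_uM, abs(ic50 - threshold_uM))

    best, best_key = x0, key(x0)
    for direction in (1, -1):
        x = x0
        for _ in range(500):
            x = math.nextafter(x, direction * math.inf)
            k = key(x)
            if k < best_key:
                best, best_key = x, k
    if best_key[0]:
        raise ConfigError("no at-threshold vector found on the passing side")
    return {**others, free_name: best}
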