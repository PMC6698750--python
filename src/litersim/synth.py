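"""Synthetic flow-cytometry datasets with controlled mean and CV.

Generates per-cell fluorescence samples with the statistical structure the
analysis pipeline assumes: ~10,000 cells per sample, right-skewed positive
distributions, unimodal and tight for feedback circuits, broad (optionally
bimodal, via a lognormal mixture) for the open-loop benchmark.  Everything is
moment-matched: for the lognormal family, ``sigma^2 = ln(1 + CV^2)`` and
``mu = ln(mean) - sigma^2/2``; for the gamma family, ``shape = 1/CV^2`` and
``scale = mean * CV^2``.

Arbitrary units are anchored so basal populations sit around 1e2 a.u. and
induced ones around 1e3-1e4 a.u., resembling flow-cytometry histogram
decades.  Data are pre-gated by construction: no instrument effects
(autofluorescence, spillover, debris) are emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAMILIES = ("lognormal", "gamma", "mixture")


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population: target moments and distribution family.

    For ``mixture``, ``components`` holds (weight, mean, cv) triples of
    lognormal components (weights must sum to 1) and the top-level
    mean/cv are ignored.
    """

    mean: float = 1000.0
    cv: float = 0.3
    n_cells: int = 10_000
    distribution: str = "lognormal"
    components: tuple[tuple[float, float, float], ...] | None = None
    dose: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.distribution not in FAMILIES:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "mixture":
            if not self.components:
                raise ValueError("mixture requires components")
            w = sum(c[0] for c in self.components)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {w}")
            for _, m, cv in self.components:
                _check_moments(m, cv)
        else:
            _check_moments(self.mean, self.cv)


def _check_moments(mean: float, cv: float) -> None:
    if not (mean > 0):
        raise ValueError(f"target mean must be > 0, got {mean}")
    if not (cv > 0):
        raise ValueError(f"target CV must be > 0, got {cv}")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def _gamma(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean * cv**2, n)


def generate_sample(spec: PopulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one per-cell fluorescence sample (positive floats, a.u.)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    if spec.distribution == "lognormal":
        return _lognormal(rng, spec.mean, spec.cv, n)
    if spec.distribution == "gamma":
        return _gamma(rng, spec.mean, spec.cv, n)
    weights = np.array([c[0] for c in spec.components])
    counts = rng.multinomial(n, weights)
    parts = [
        _lognormal(rng, m, cv, k)
        for (w, m, cv), k in zip(spec.components, counts)
        if k > 0
    ]
    values = np.concatenate(parts)
    rng.shuffle(values)
    return values


def _as_profile(profile) -> callable:
    if callable(profile):
        return profile
    if isinstance(profile, dict):
        return lambda d: profile[d]
    return lambda d: float(profile)  # scalar


def generate_experiment(
    response,
    cv_profile,
    doses,
    replicates: int = 3,
    n_cells: int = 10_000,
    seed: int = 0,
    distribution: str = "lognormal",
) -> tuple[pd.DataFrame, dict]:
    """Full titration dataset: one cell sample per dose x replicate.

    Parameters
    ----------
    response
        Mean fluorescence vs dose: a callable, a dose->mean dict, or a
        dose-response DataFrame from the deterministic engine.
    cv_profile
        CV vs dose: callable, dict, or scalar.
    doses, replicates
        Dose grid and replicate count (flow experiments here use N = 3).

    Returns
    -------
    (dataset, manifest)
        ``dataset`` uses the shared per-cell schema (dose, replicate,
        cell_id, fluorescence); ``manifest`` records every per-sample seed,
        so any sample can be regenerated in isolation.
    """
    if isinstance(response, pd.DataFrame):
        col = "value" if "value" in response.columns else "gfp"
        table = dict(zip(response["dose"], response[col]))
        response = table
    mean_of = _as_profile(response)
    cv_of = _as_profile(cv_profile)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(list(doses)) * replicates)
    frames = []
    manifest = {"seed": seed, "replicates": replicates, "n_cells": n_cells,
                "distribution": distribution, "samples": []}
    k = 0
    for dose in doses:
        for rep in range(1, replicates + 1):
            child = children[k]
            k += 1
            spec = PopulationSpec(
                mean=float(mean_of(dose)), cv=float(cv_of(dose)),
                n_cells=n_cells, distribution=distribution, dose=dose,
            )
            values = generate_sample(spec, np.random.default_rng(child))
            frames.append(pd.DataFrame({
                "dose": dose, "replicate": rep,
                "cell_id": np.arange(n_cells), "fluorescence": values,
            }))
            manifest["samples"].append({
                "dose": float(dose), "replicate": rep,
                "target_mean": spec.mean, "target_cv": spec.cv,
                "seed_entropy": int(child.entropy),
                "spawn_key": [int(x) for x in child.spawn_key],
            })
    return pd.concat(frames, ignore_index=True), manifest


def summarize_experiment(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-(dose, replicate) mean and CV table from a per-cell dataset."""
    required = {"dose", "replicate", "fluorescence"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"per-cell dataset is missing columns: {sorted(missing)}")
    if dataset.empty:
        raise ValueError("per-cell dataset is empty")
    g = dataset.groupby(["dose", "replicate"])["fluorescence"]
    out = g.agg(mean="mean", std=lambda v: v.std(ddof=1)).reset_index()
    out["cv"] = out["std"] / out["mean"]
    out["value"] = out["mean"]
    return out[["dose", "replicate", "mean", "cv", "value"]]
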