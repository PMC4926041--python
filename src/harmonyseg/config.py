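"""Shared configuration: namespaced hyperparameters for all stages.

A config is a flat mapping with three namespaces — ``hs.*`` for the
harmony-search hyperparameters, ``rough.*`` for the rough-set memory
construction and ``fcm.*`` for fuzzy c-means — plus ``pipeline.fitness``
selecting the clustering fitness metric. YAML files may spell the keys
either nested (sections) or dotted; both parse to the same flat dict,
and ``save_config`` followed by ``load_config`` is the identity.
"""

from __future__ import annotations

from typing import Mapping, Tuple

import numpy as np
import yaml

from .fcm import FCMParams
from .hs import HSParams
from .rough import RoughParams

__all__ = ["DEFAULTS", "load_config", "save_config", "build_params"]

DEFAULTS: dict = {
    "hs.hms": 30,
    "hs.hmcr": 0.9,
    "hs.par_min": 0.3,
    "hs.par_max": 0.9,
    "hs.bw_min": 0.01,
    "hs.bw_max": 0.1,
    "hs.max_iterations": 2000,
    "rough.boundary_threshold": 0.05,
    "rough.w_low": 0.75,
    "rough.knn_k": 5,
    "rough.max_rounds": 100,
    "rough.stop_threshold": 1e-4,
    "fcm.fuzzifier": 2.0,
    "fcm.epsilon": 1e-5,
    "fcm.max_iter": 100,
    "pipeline.fitness": "l2",
}


def _flatten(mapping: Mapping, prefix: str = "") -> dict:
    flat = {}
    for key, value in mapping.items():
        name = f"{prefix}{key}"
        if isinstance(value, Mapping):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = value
    return flat


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Load a config file (or nothing) on top of the defaults.

    Unknown keys are rejected so typos fail loudly.
    """
    cfg = dict(DEFAULTS)
    layers = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        layers.append(_flatten(loaded))
    if overrides:
        layers.append(_flatten(overrides))
    for layer in layers:
        for key, value in layer.items():
            if key not in DEFAULTS:
                raise KeyError(f"unknown config key {key!r}")
            cfg[key] = value
    return cfg


def save_config(cfg: Mapping, path) -> None:
    """Write a flat config as dotted-key YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def build_params(
    cfg: Mapping, c: int, seed: int, feature_dim: int = 1
) -> Tuple[HSParams, RoughParams, FCMParams]:
    """Instantiate stage parameter objects for a c-cluster segmentation.

    The harmony vectors encode the concatenated cluster centers over the
    normalized intensity range, so ``n_dims = c * feature_dim`` with
    bounds [0, 1]. Stage seeds are decorrelated children of ``seed``.
    """
    cfg = {**DEFAULTS, **dict(cfg)}
    hs_seed, rough_seed, fcm_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(3) % (2**31)
    )
    hs = HSParams(
        n_dims=c * feature_dim,
        lower_bound=np.zeros(c * feature_dim),
        upper_bound=np.ones(c * feature_dim),
        hms=int(cfg["hs.hms"]),
        hmcr=float(cfg["hs.hmcr"]),
        par_min=float(cfg["hs.par_min"]),
        par_max=float(cfg["hs.par_max"]),
        bw_min=float(cfg["hs.bw_min"]),
        bw_max=float(cfg["hs.bw_max"]),
        max_iterations=int(cfg["hs.max_iterations"]),
        seed=hs_seed,
    )
    rough = RoughParams(
        k_clusters=c,
        boundary_threshold=float(cfg["rough.boundary_threshold"]),
        w_low=float(cfg["rough.w_low"]),
        knn_k=int(cfg["rough.knn_k"]),
        max_rounds=int(cfg["rough.max_rounds"]),
        stop_threshold=float(cfg["rough.stop_threshold"]),
        seed=rough_seed,
    )
    fcm = FCMParams(
        c=c,
        fuzzifier=float(cfg["fcm.fuzzifier"]),
        epsilon=float(cfg["fcm.epsilon"]),
        max_iter=int(cfg["fcm.max_iter"]),
        seed=fcm_seed,
    )
    return hs, rough, fcm
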