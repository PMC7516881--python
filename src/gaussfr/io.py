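"""JSON schemas for Gaussians and diagonal mixtures.

Gaussian:  {"mu": [..], "sigma": [[..], [..]]}          (row-major)
DGMM:      {"weights": [..],
            "components": [{"mu": [..], "sigma_diag": [..]}, ...]}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Gaussian
from .mixtures import DGMM

__all__ = [
    "gaussian_to_dict",
    "gaussian_from_dict",
    "load_gaussian",
    "save_gaussian",
    "dgmm_to_dict",
    "dgmm_from_dict",
    "load_dgmm",
    "save_dgmm",
]


def gaussian_to_dict(theta: Gaussian) -> dict:
    return {"mu": theta.mu.tolist(), "sigma": theta.sigma.tolist()}


def gaussian_from_dict(d: dict) -> Gaussian:
    return Gaussian(d["mu"], d["sigma"])


def load_gaussian(path) -> Gaussian:
    return gaussian_from_dict(json.loads(Path(path).read_text()))


def save_gaussian(theta: Gaussian, path) -> None:
    Path(path).write_text(json.dumps(gaussian_to_dict(theta), indent=1))


def dgmm_to_dict(f: DGMM) -> dict:
    return {
        "weights": f.weights.tolist(),
        "components": [
            {"mu": c.mu.tolist(), "sigma_diag": np.diag(c.sigma).tolist()}
            for c in f.components
        ],
    }


def dgmm_from_dict(d: dict) -> DGMM:
    comps = tuple(
        Gaussian(c["mu"], np.diag(c["sigma_diag"])) for c in d["components"]
    )
    return DGMM(np.asarray(d["weights"], dtype=float), comps)


def load_dgmm(path) -> DGMM:
    return dgmm_from_dict(json.loads(Path(path).read_text()))


def save_dgmm(f: DGMM, path) -> None:
    Path(path).write_text(json.dumps(dgmm_to_dict(f), indent=1))
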