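"""TOML run configuration with explicit unit suffixes, plus run metadata.

Config keys carry their unit in the name (``E_Pa``, ``radius_um``, ...), so a
config file is unambiguous to audit.  :func:`resolve_config` merges user
values over the defaults and converts to SI; every run writes a metadata
record (resolved config + package version) alongside its outputs.
"""

from __future__ import annotations

import json
import os
import tomllib

DEFAULTS: dict = {
    "material": {"E_Pa": 140.0, "nu": 0.48, "w": 1.0},
    "geometry": {"radius_um": 8.6, "subdivisions": 3, "probe_radius_um": 26.5},
    "protocol": {
        "increment": 0.005,
        "max_deformation": 0.6,
        "residual_tol": 1e-4,
        "max_relax_steps": 20000,
        "contact_stiffness_factor": 100.0,
    },
    "flow": {
        "ca": 0.2,
        "cells": 1,
        "box": [10, 15, 5],
        "resolution": 5,
        "mesh_subdivisions": 2,
        "tau": 1.0,
        "u_wall": 0.04,
        "duration": 10.0,
        "transient": 5.0,
        "eta_Pa_s": 1e-3,
        "rho_kg_m3": 1e3,
        "gamma_dot_per_s": 4.0,
    },
    "seed": 0,
}

_KNOWN_SECTIONS = set(DEFAULTS)


def load_config(path: str | os.PathLike | None) -> dict:
    """Read a TOML config file (or return {} for None)."""
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def resolve_config(user: dict | None = None) -> dict:
    """Merge user values over the defaults; reject unknown keys."""
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    user = user or {}
    for section, values in user.items():
        if section not in _KNOWN_SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(values, dict):
            for key, val in values.items():
                if key not in cfg[section]:
                    raise ValueError(
                        f"unknown config key {section}.{key!r}")
                cfg[section][key] = val
        else:
            cfg[section] = values
    return cfg


def write_metadata(path: str | os.PathLike, cfg: dict, extra: dict | None = None) -> None:
    """Write the resolved config + package version as a JSON record."""
    from . import __version__

    record = {"package": "hypercell", "version": __version__, "config": cfg}
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    try:
        import numpy as np

        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
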