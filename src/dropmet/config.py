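"""Run configuration: nested defaults, YAML loading, strict key checking."""

from __future__ import annotations

import copy

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "droplet_diameter": 35.0,  # um
        "aqueous_flow": 4.0,  # ul/min
        "run_time": 10.0,  # min
        "occupied_fraction": 0.10,  # fraction of droplets with >= 1 cell
        "bead_occupancy": 0.07,
        "fusion_efficiency": 0.80,
        "barcode_droplet_rate": 132.0,  # droplets/s
        "n_beads": 20_000,
    },
    "genome": {
        "n_contigs": 4,
        "contig_length": 150_000,
        "gc_fraction": 0.42,
        "n_species": 1,
        "spike_length": 48_000,
    },
    "methylome": {
        # (name, global mCG target, global mCH target)
        "type_specs": [
            ["typeA", 0.505, 0.010],
            ["typeB", 0.682, 0.011],
            ["typeC", 0.630, 0.009],
        ],
        "n_dmrs": 8,
        "dmr_length": 2_000,
        "dmr_depth": 0.4,
    },
    "experiment": {
        "n_cells_by_type": {"typeA": 200, "typeB": 200, "typeC": 200},
    },
    "reads": {
        "read_length": 150,
        "reads_per_cell": 2_000,
        "conversion_rate": 0.99,
        "seq_error": 0.001,
        "duplication_rate": 0.1,
        "frag_mean": 300.0,
        "frag_sd": 80.0,
        "min_frag": 150,
        "spike_fraction": 0.05,
        "contamination_rate": 0.01,
    },
    "align": {"k": 24, "max_edit": 3},
    "cellcall": {"multiplier": 2.5, "k_range": [2, 3, 4], "purity_threshold": 0.90},
    "cluster": {
        "bin_width": 100_000,
        "cls": "CG",
        "min_sites_per_bin": 20,
        "min_cell_fraction_per_bin": 0.5,
        "n_pcs": 50,
        "knn_k": 15,
        "resolution": 1.0,
        "z_threshold": -1.0,
    },
    "dmr": {
        "min_cov": 5,
        "fdr": 0.05,
        "min_delta": 0.1,
        "merge_dist": 500,
        "min_cpgs": 3,
    },
}


def _merge_checked(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and key not in (
            "n_cells_by_type",
        ):
            if not isinstance(val, dict):
                raise TypeError(f"{here} must be a mapping")
            out[key] = _merge_checked(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and/or a dict; unknown keys raise."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = _merge_checked(cfg, data)
    if overrides:
        cfg = _merge_checked(cfg, overrides)
    return cfg
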