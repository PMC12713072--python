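"""Configuration files and simulation outputs.

Scenario files are YAML with sections mirroring the parameter blocks
(formulation / vial / thermo / transport / nucleation / desorption /
numerics) plus the stage protocols.  Outputs are plain CSV tables with a
JSON run manifest (schema version, configuration hash, seed) so a run can
be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .cases import CaseSpec, case_from_dict, case_to_dict

SCHEMA_VERSION = 1


def write_config(path, case: CaseSpec) -> None:
    """Write a scenario (configuration + protocols) to a YAML file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(case_to_dict(case), fh, sort_keys=False)


def read_config(path) -> CaseSpec:
    """Read a scenario from a YAML file written by :func:`write_config`."""
    with open(path) as fh:
        return case_from_dict(yaml.safe_load(fh))


def config_hash(case: CaseSpec) -> str:
    """Stable short hash of a scenario for run manifests."""
    blob = json.dumps(case_to_dict(case), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_outputs(outdir, case: CaseSpec, tables: dict, scalars: dict,
                  seed=None) -> Path:
    """Write result tables (CSV), summary scalars and a run manifest.

    Parameters
    ----------
    tables : dict
        Mapping of file stem -> pandas DataFrame.
    scalars : dict
        Summary scalars written to ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(scalars, fh, indent=2, default=float)
    manifest = {"schema_version": SCHEMA_VERSION, "case": case.name,
                "config_hash": config_hash(case), "seed": seed}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
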