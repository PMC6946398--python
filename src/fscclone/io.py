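"""Table and manifest I/O.

Exchange dialect: tab-separated tables with one header line (lines starting
with ``#`` are metadata comments), JSON for nested reports, YAML for
configuration, multi-channel TIFF for image stacks.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .germarium import AnteriorAnnotation, ClonePatch, OvarioleRecord, SimConfig
from .marker_models import Phenotype

__all__ = [
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_manifest",
    "load_config",
    "sim_config_from_dict",
]

_PATCH_COLS = [
    "ovariole_id",
    "dphs",
    "condition",
    "total_cells_scored",
    "follicle_cells_scored",
    "background_phenotype",
    "anterior_cell_position",
    "ant_fasiii",
    "ant_at_boundary",
    "ant_contiguous",
    "patch_id",
    "phenotype",
    "touches_border",
    "n_follicles_spanned",
    "fraction_of_follicle",
    "cell_count",
    "in_germarium_only",
    "contiguous_with",
]


def _pheno_str(p: Optional[Phenotype]) -> str:
    if p is None:
        return ""
    return p.label()


def _pheno_parse(s: str) -> Optional[Phenotype]:
    if s == "" or pd.isna(s):
        return None
    if s == "(none)":
        return Phenotype.of()
    return Phenotype(frozenset(s.split("+")))


def write_cohort_tsv(cohort, path) -> None:
    """Write a cohort (list of per-ovariole record lists, or flat record
    list) as one patch-per-row TSV; patch-free records get a sentinel row
    with patch_id = -1 so they survive the round trip."""
    records = []
    if cohort and isinstance(cohort[0], OvarioleRecord):
        records = list(cohort)
    else:
        records = [r for ov in cohort for r in ov]
    rows = []
    for r in records:
        ann = r.anterior_annotation
        base = {
            "ovariole_id": r.ovariole_id,
            "dphs": r.dphs,
            "condition": r.condition,
            "total_cells_scored": r.total_cells_scored,
            "follicle_cells_scored": r.follicle_cells_scored,
            "background_phenotype": _pheno_str(r.background_phenotype),
            "anterior_cell_position": r.anterior_cell_position,
            "ant_fasiii": "" if ann is None else int(ann.fasiii_positive),
            "ant_at_boundary": "" if ann is None else int(ann.at_boundary),
            "ant_contiguous": "" if ann is None else int(ann.contiguous_with_clone),
        }
        if not r.patches:
            rows.append(
                base
                | {
                    "patch_id": -1,
                    "phenotype": "",
                    "touches_border": 0,
                    "n_follicles_spanned": 0,
                    "fraction_of_follicle": "",
                    "cell_count": 0,
                    "in_germarium_only": 0,
                    "contiguous_with": "",
                }
            )
            continue
        for p in r.patches:
            rows.append(
                base
                | {
                    "patch_id": p.patch_id,
                    "phenotype": _pheno_str(p.phenotype),
                    "touches_border": int(p.touches_border),
                    "n_follicles_spanned": p.n_follicles_spanned,
                    "fraction_of_follicle": ",".join(
                        f"{f:.6g}" for f in p.fraction_of_follicle
                    ),
                    "cell_count": p.cell_count,
                    "in_germarium_only": int(p.in_germarium_only),
                    "contiguous_with": ""
                    if p.contiguous_with is None
                    else p.contiguous_with,
                }
            )
    df = pd.DataFrame(rows, columns=_PATCH_COLS)
    with open(path, "w") as fh:
        fh.write(f"# fscclone cohort table v{__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_cohort_tsv(path) -> list[OvarioleRecord]:
    """Read a cohort TSV back into a flat list of OvarioleRecords."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    records: list[OvarioleRecord] = []
    for (ovid, dphs), grp in df.groupby(["ovariole_id", "dphs"], sort=True):
        first = grp.iloc[0]
        ann = None
        if first["ant_fasiii"] != "":
            ann = AnteriorAnnotation(
                fasiii_positive=bool(int(first["ant_fasiii"])),
                at_boundary=bool(int(first["ant_at_boundary"])),
                contiguous_with_clone=bool(int(first["ant_contiguous"])),
            )
        patches = []
        for _, row in grp.iterrows():
            if int(row["patch_id"]) < 0:
                continue
            fracs = (
                [float(f) for f in str(row["fraction_of_follicle"]).split(",")]
                if row["fraction_of_follicle"] != ""
                else []
            )
            patches.append(
                ClonePatch(
                    phenotype=_pheno_parse(row["phenotype"]),
                    touches_border=bool(int(row["touches_border"])),
                    n_follicles_spanned=int(row["n_follicles_spanned"]),
                    fraction_of_follicle=fracs,
                    cell_count=int(row["cell_count"]),
                    in_germarium_only=bool(int(row["in_germarium_only"])),
                    contiguous_with=None
                    if row["contiguous_with"] == ""
                    else int(row["contiguous_with"]),
                    patch_id=int(row["patch_id"]),
                )
            )
        labeled: dict[Phenotype, int] = {}
        for p in patches:
            labeled[p.phenotype] = labeled.get(p.phenotype, 0) + p.cell_count
        records.append(
            OvarioleRecord(
                dphs=float(dphs),
                patches=patches,
                total_cells_scored=int(first["total_cells_scored"]),
                labeled_cells=labeled,
                anterior_cell_position=str(first["anterior_cell_position"]),
                anterior_annotation=ann,
                background_phenotype=_pheno_parse(first["background_phenotype"]),
                follicle_cells_scored=int(first["follicle_cells_scored"]),
                ovariole_id=int(ovid),
                condition=str(first["condition"]),
            )
        )
    return records


def write_manifest(
    out_dir,
    subcommand: str,
    config: dict,
    seed: Optional[int],
    inputs: Optional[dict] = None,
    outputs: Optional[dict] = None,
) -> Path:
    """Write the run manifest (config echo, seed, paths, timestamp)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "fscclone",
        "version": __version__,
        "subcommand": subcommand,
        "config": config,
        "master_seed": seed,
        "inputs": inputs or {},
        "outputs": outputs or {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


class SchemaError(ValueError):
    """Config is missing required keys."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(f"config missing required keys: {', '.join(missing)}")


def require_keys(cfg: dict, keys: list[str]) -> None:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise SchemaError(missing)


def sim_config_from_dict(cfg: dict) -> SimConfig:
    """Build a SimConfig from a plain dict, ignoring non-SimConfig keys."""
    names = {f.name for f in dataclasses.fields(SimConfig)}
    kw = {k: v for k, v in cfg.items() if k in names}
    if "heat_shock_times_h" in kw:
        kw["heat_shock_times_h"] = tuple(kw["heat_shock_times_h"])
    if "sample_dphs" in kw:
        kw["sample_dphs"] = tuple(kw["sample_dphs"])
    return SimConfig(**kw)
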