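"""Dataset readers/writers, run configuration, and the packaged AhR table.

Structures arrive as SDF V2000 with explicit 3D coordinates, per-carbon
¹³C shifts and activities as CSV (UTF-8, comma, header row, "." decimal);
the three sources are joined on compound id.  Shift prediction and
conformer generation are deliberately out of scope — shifts and geometries
are inputs.

The packaged fixture ``ahr_table2.csv`` carries the 94 aryl-hydrocarbon-
receptor binders with their experimental log(1/EC50) and the four composite
prediction columns (PLS/KNN at 2 ppm and 10 ppm × 0.5 Å) plus the printed
consensus column; rows with known typesetting artifacts are flagged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fingerprint import Compound

logger = logging.getLogger("sdar3d")

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_sdf",
    "write_report",
    "load_ahr_table",
]


@dataclass
class RunConfig:
    """Everything a full modeling run needs, JSON round-trippable."""

    seed: int
    structures: str = ""
    shifts: str = ""
    activities: str = ""
    xy_widths: list[float] = field(default_factory=lambda: [2, 4, 6, 8, 10, 12, 14, 16, 18, 20])
    z_heights: list[float] = field(default_factory=lambda: [0.5, 1.0, 1.5, 2.0, 2.5])
    n_cycles: int = 100
    test_fraction: float = 0.2
    lv_max: int = 10
    k_max: int = 10
    r2_mode: str = "pearson_sq"
    outdir: str = "results"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, doc: str) -> "RunConfig":
        return cls(**json.loads(doc))


def read_dataset(structures: str, shifts: str, activities: str) -> list[Compound]:
    """Join SDF structures, shift table, and activity table into Compounds.

    The shift table must list one row per carbon atom (0-based ``atom_index``
    into the SDF atom order).  Compounds missing from the activity table are
    loaded with ``activity=None`` and should be excluded from modeling;
    structural or shift-count problems are collected and reported per
    compound in a single error.
    """
    from rdkit import Chem

    shift_df = pd.read_csv(shifts)
    act_df = pd.read_csv(activities).set_index("compound_id")
    shift_map: dict[str, dict[int, float]] = {}
    for cid, grp in shift_df.groupby("compound_id"):
        shift_map[str(cid)] = dict(zip(grp["atom_index"].astype(int), grp["shift_ppm"].astype(float)))

    supplier = Chem.SDMolSupplier(str(structures), removeHs=False, sanitize=False)
    compounds: list[Compound] = []
    problems: list[str] = []
    seen_ids: set[str] = set()
    for mol in supplier:
        if mol is None:
            problems.append("unparseable SDF record")
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{len(compounds)}"
        seen_ids.add(cid)
        if mol.GetNumConformers() == 0:
            problems.append(f"{cid}: no coordinates in SDF record")
            continue
        conf = mol.GetConformer()
        if not conf.Is3D():
            problems.append(f"{cid}: SDF record is not 3D")
            continue
        symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
        carbon_idx = [i for i, s in enumerate(symbols) if s == "C"]
        per_atom = shift_map.get(cid, {})
        missing = [i for i in carbon_idx if i not in per_atom]
        extra = [i for i in per_atom if i not in carbon_idx]
        if missing or extra:
            problems.append(
                f"{cid}: shift table mismatch — {len(per_atom)} shifts for "
                f"{len(carbon_idx)} carbons (missing atoms {missing}, non-carbon entries {extra})"
            )
            continue
        activity = float(act_df.loc[cid, "activity"]) if cid in act_df.index else None
        if activity is None:
            logger.warning("%s: no activity entry; loaded but excluded from modeling", cid)
        try:
            compounds.append(
                Compound(
                    id=cid,
                    element_symbols=symbols,
                    coordinates=coords,
                    carbon_shifts=tuple(per_atom[i] for i in carbon_idx),
                    activity=activity,
                )
            )
        except ValueError as err:
            problems.append(str(err))
    unmatched = sorted(set(act_df.index.astype(str)) - seen_ids)
    if unmatched:
        logger.warning("activity ids without structures: %s", unmatched)
    if problems:
        raise ValueError("dataset validation failed:\n  " + "\n  ".join(problems))
    return compounds


def write_sdf(compounds: list[Compound], path: str) -> None:
    """Write compounds as a 3D SDF V2000 file (atoms only, no bonds)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    with Chem.SDWriter(str(path)) as writer:
        for c in compounds:
            mol = Chem.RWMol()
            for s in c.element_symbols:
                mol.AddAtom(Chem.Atom(s))
            conf = Chem.Conformer(len(c.element_symbols))
            for i, (x, y, z) in enumerate(np.asarray(c.coordinates)):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            conf.Set3D(True)
            mol.AddConformer(conf)
            m = mol.GetMol()
            m.SetProp("_Name", c.id)
            m.UpdatePropertyCache(strict=False)
            writer.write(m)


def write_report(
    outdir: str,
    config: RunConfig,
    predictions: Optional[pd.DataFrame] = None,
    scan_table: Optional[pd.DataFrame] = None,
    consensus_table: Optional[pd.DataFrame] = None,
    attributions: Optional[pd.DataFrame] = None,
) -> list[Path]:
    """Write the run's CSV outputs plus a log of the seed and configuration.

    Files are written deterministically (stable row/column order from the
    inputs) so identical runs produce byte-identical outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in (
        ("predictions.csv", predictions),
        ("scan.csv", scan_table),
        ("consensus.csv", consensus_table),
        ("attributions.csv", attributions),
    ):
        if df is not None:
            path = out / name
            df.to_csv(path, index=False)
            written.append(path)
    log_path = out / "run.json"
    log_path.write_text(config.to_json() + "\n")
    written.append(log_path)
    return written


def load_ahr_table(dedupe: bool = False) -> pd.DataFrame:
    """Load the packaged 94-compound AhR prediction table.

    Columns: compound_id, experimental, pls_2ppm, knn_2ppm, pls_10ppm,
    knn_10ppm, consensus, flag.  The printed consensus is the half-up
    rounded mean of knn_2ppm and pls_10ppm.  ``flag`` marks the truncated
    compound name, repeated congener names, and the two rows whose printed
    consensus disagrees with re-derivation by 0.01.  With ``dedupe=True``
    rows flagged ``duplicate_name`` are dropped (first occurrence kept).
    """
    with resources.files("sdar3d.data").joinpath("ahr_table2.csv").open("r") as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    if dedupe:
        df = df[~df["flag"].str.contains("duplicate_name")].reset_index(drop=True)
    return df
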