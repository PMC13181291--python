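"""One-shot evaluation report: contours, CT numbers, DVH and gamma.

``run_report`` orchestrates the per-domain evaluation modules over a
reference/test pair (typically refCT vs synthetic CT and the doses
recalculated on each) and writes CSV tables plus a JSON manifest.  Given
identical inputs and configuration the outputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contour_eval import contour_metrics
from .core import DoseGrid, ImageVolume, StructureSet
from .dose_eval import GammaCriteria, dose_stats, gamma_summary
from .hu_eval import hu_difference
from .io import FOVSpec, crop_structures, crop_to_fov


@dataclass(frozen=True)
class RunConfig:
    """Inputs of a full evaluation run (in-memory objects)."""

    seed: int
    ref_volume: ImageVolume
    test_volume: ImageVolume
    ref_structures: StructureSet
    test_structures: StructureSet
    ref_dose: DoseGrid
    test_dose: DoseGrid
    gtv_structure: str
    criteria: tuple[GammaCriteria, ...] = (
        GammaCriteria(3.0, 3.0), GammaCriteria(2.0, 2.0), GammaCriteria(1.0, 2.0))
    fov: FOVSpec | None = None
    extra: dict = field(default_factory=dict)


def run_report(cfg: RunConfig, out_dir) -> dict[str, pd.DataFrame]:
    """Run every evaluation stage and write the report bundle.

    Stages: optional FOV cropping, contour metrics (DSC/MDA/HD with the
    DSC > 0.8 and MDA < 2 mm flags), per-structure mean-HU differences,
    GTV DVH statistics, and the gamma pass-rate summary.  Any stage error
    is re-raised with the stage name attached.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_vol, test_vol = cfg.ref_volume, cfg.test_volume
    ref_structs, test_structs = cfg.ref_structures, cfg.test_structures
    if cfg.fov is not None:
        ref_vol = crop_to_fov(ref_vol, cfg.fov)
        test_vol = crop_to_fov(test_vol, cfg.fov)
        ref_structs = crop_structures(ref_structs, cfg.fov)
        test_structs = crop_structures(test_structs, cfg.fov)

    tables: dict[str, pd.DataFrame] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"report stage {name!r} failed: {exc}") from exc

    def _contours():
        rows = []
        for name in ref_structs.names():
            if name not in test_structs:
                continue
            m = contour_metrics(name, ref_structs[name], test_structs[name],
                                ref_structs.grid.spacing, ref_structs.grid.origin)
            rows.append({
                "structure": name, "dsc": m.dsc, "mda_mm": m.mda_mm,
                "hd_mm": m.hd_mm, "dsc_pass": m.dsc_pass, "mda_pass": m.mda_pass,
            })
        return pd.DataFrame(rows)

    tables["contour_metrics"] = stage("contours", _contours)
    tables["hu_differences"] = stage(
        "hu", lambda: hu_difference(ref_vol, test_vol, ref_structs))

    def _dose():
        s = dose_stats(cfg.ref_dose, cfg.test_dose,
                       ref_structs[cfg.gtv_structure])
        return pd.DataFrame([vars(s)])

    tables["dose_stats"] = stage("dvh", _dose)
    tables["gamma_summary"] = stage(
        "gamma", lambda: gamma_summary(cfg.ref_dose, cfg.test_dose,
                                       list(cfg.criteria)))

    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {
        "seed": cfg.seed,
        "sctkit_version": __version__,
        "gtv_structure": cfg.gtv_structure,
        "criteria": [c.label for c in cfg.criteria],
        "structures": ref_structs.names(),
        "tables": sorted(tables),
    }
    manifest.update(cfg.extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    return tables
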