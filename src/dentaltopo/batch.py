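"""Batch analysis driver: any combination of DNE, RFI, OPCR per mesh.

Each PLY in a directory is processed independently (no cross-file state);
per-file failures are logged and recorded as NA rows without aborting the
batch, and results are written as a TSV in deterministic (lexicographic)
order so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import dne as dne_mod
from . import io as mesh_io
from . import opcr as opcr_mod
from . import rfi as rfi_mod
from .mesh import TriangleMesh

log = logging.getLogger("dentaltopo")


@dataclass
class RunConfig:
    """Configuration of one batch run."""

    metrics: frozenset = frozenset({"DNE", "RFI", "OPCR"})
    dne_options: dne_mod.DNEOptions = field(default_factory=dne_mod.DNEOptions)
    rfi_resolution: int = 1000
    opcr_min_patch_size: int = 5

    def __post_init__(self) -> None:
        bad = set(self.metrics) - {"DNE", "RFI", "OPCR"}
        if bad:
            raise ValueError(f"unknown metrics: {sorted(bad)}")
        if not self.metrics:
            raise ValueError("at least one metric must be enabled")

    def provenance(self) -> list[str]:
        o = self.dne_options
        return [
            f"metrics={'+'.join(sorted(self.metrics))}",
            f"dne: boundary_discard={o.boundary_discard} condition_check={o.condition_check}"
            f" condition_threshold={o.condition_threshold:g}"
            f" outlier_discard={o.outlier_discard} outlier_percentile={o.outlier_percentile}"
            f" outlier_basis={o.outlier_basis} smooth_first={o.smooth_first}",
            f"rfi: resolution={self.rfi_resolution}",
            f"opcr: min_patch_size={self.opcr_min_patch_size}",
        ]


def analyze_mesh(mesh: TriangleMesh, config: RunConfig | None = None
                 ) -> mesh_io.ResultRecord:
    """Run the enabled metrics on one mesh."""
    cfg = config or RunConfig()
    rec = mesh_io.ResultRecord(specimen_name=mesh.name)
    if "DNE" in cfg.metrics:
        rec.dne = dne_mod.compute_dne(mesh, cfg.dne_options).total_dne
    if "RFI" in cfg.metrics:
        r = rfi_mod.compute_rfi(mesh, cfg.rfi_resolution)
        rec.rfi, rec.area_3d, rec.area_2d = r.rfi_ratio, r.area_3d, r.area_2d
    if "OPCR" in cfg.metrics:
        r = opcr_mod.compute_opcr(mesh, cfg.opcr_min_patch_size)
        rec.opcr, rec.opc_per_rotation = r.opcr, r.opc_per_rotation
    return rec.check()


def run_batch(input_path, output_path=None, config: RunConfig | None = None
              ) -> tuple[list[mesh_io.ResultRecord], int]:
    """Analyze one PLY file or every .ply in a directory.

    Returns (records, n_failures).  Failed files produce an all-NA record
    and a logged error; they never abort the batch.  When ``output_path``
    is given the records are written there as TSV with the run options as
    header comments.
    """
    cfg = config or RunConfig()
    input_path = Path(input_path)
    if input_path.is_dir():
        files = sorted(input_path.glob("*.ply"))
        if not files:
            raise FileNotFoundError(f"no .ply files in {input_path}")
    else:
        files = [input_path]
    records: list[mesh_io.ResultRecord] = []
    failures = 0
    for f in files:
        try:
            mesh = mesh_io.read_ply(f)
            records.append(analyze_mesh(mesh, cfg))
        except Exception as exc:  # contain per-file failures
            log.error("%s: %s", f.name, exc)
            failures += 1
            records.append(mesh_io.ResultRecord(specimen_name=f.stem))
    if output_path is not None:
        mesh_io.write_results_tsv(records, output_path,
                                  header_comments=cfg.provenance())
    return records, failures
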