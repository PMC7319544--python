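"""End-to-end analysis runs and the local results bundle.

A run takes a wildtype sequence, a mutation code and folding/scan/render
settings, and produces a directory with figures (PNG/SVG), TSV tables,
the impact-report JSON, a run log, an echoed configuration and a ZIP of
everything, with a manifest listing the bundle contents exactly.

Two backends exist: ``internal`` folds both sequences with this package's
partition-function engine; ``dotplot-files`` instead ingests a pair of
externally produced dot-plot files (e.g. from RNAplfold) and computes the
differential representations and the region scan from those matrices
(relative entropy and empirical p-values need refolding and are omitted
there).
"""

from __future__ import annotations

import json
import logging
import platform
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .diff import build_diff_result
from .dotplot import read_ps_dotplot, write_ps_dotplot, write_tsv_outputs
from .energy import get_model
from .fold import (
    AccessibilityProfile,
    FoldingParams,
    accessibility_profile,
    pair_probabilities_local,
)
from .impact import (
    ImpactReport,
    build_impact_report,
    region_distance_scan,
)
from .render import (
    RenderSpec,
    render_accessibility,
    render_arc_diagram,
    render_circular,
    render_diff_heatmap,
    render_heatmap,
)
from .sequences import (
    MutationSpec,
    RnaSequence,
    apply_mutations,
    parse_mutation_code,
    read_fasta,
)

__all__ = ["RunConfig", "RunResult", "run_analysis"]

logger = logging.getLogger("mutfold")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    fasta: str | Path
    mutation: str
    params: FoldingParams = field(default_factory=FoldingParams)
    model_id: str = "stacking"
    scan_window_lengths: tuple = (50,)
    scan_step: int = 5
    render: RenderSpec = field(default_factory=RenderSpec)
    out_dir: str | Path = "mutfold_results"
    backend: str = "internal"
    wt_dotplot: str | Path | None = None
    mut_dotplot: str | Path | None = None
    seed: int = 0
    make_plots: bool = True
    compute_pvalues: bool = True

    def __post_init__(self) -> None:
        if self.backend not in ("internal", "dotplot-files"):
            raise ValueError(
                f"backend must be 'internal' or 'dotplot-files', got {self.backend!r}"
            )
        if self.backend == "dotplot-files" and (
            self.wt_dotplot is None or self.mut_dotplot is None
        ):
            raise ValueError(
                "backend 'dotplot-files' requires both wt_dotplot and mut_dotplot"
            )

    def echo(self) -> dict:
        return {
            "tool": "mutfold",
            "version": __version__,
            "fasta": str(self.fasta),
            "mutation": self.mutation,
            "window": self.params.window,
            "max_span": self.params.max_span,
            "u_lengths": list(self.params.u_lengths),
            "model_id": self.model_id,
            "scan_window_lengths": list(self.scan_window_lengths),
            "scan_step": self.scan_step,
            "formats": list(self.render.formats),
            "backend": self.backend,
            "wt_dotplot": str(self.wt_dotplot) if self.wt_dotplot else None,
            "mut_dotplot": str(self.mut_dotplot) if self.mut_dotplot else None,
            "seed": self.seed,
            "make_plots": self.make_plots,
            "compute_pvalues": self.compute_pvalues,
        }


@dataclass
class RunResult:
    out_dir: Path
    files: list
    report: ImpactReport | None
    bundle_zip: Path


def _figure_stems(prefix: str) -> dict:
    return {name: f"{prefix}_{name}" for name in (
        "wt", "mut", "combined", "diff", "weakened", "strengthened",
        "circular", "arcs", "accessibility",
    )}


def run_analysis(config: RunConfig) -> RunResult:
    """Execute a full analysis run and write the results bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out_dir, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path, log_path: Path) -> RunResult:
    logger.info(
        "mutfold %s on python %s / numpy %s",
        __version__, platform.python_version(), np.__version__,
    )
    logger.info("config: %s", json.dumps(config.echo()))

    wt = read_fasta(config.fasta)
    spec = parse_mutation_code(config.mutation)
    mut = apply_mutations(wt, spec)
    model = get_model(config.model_id)
    params = config.params
    logger.info("WT %s (n=%d), mutation %s", wt.id, wt.n, spec.code())

    report: ImpactReport | None = None
    if config.backend == "internal":
        wt_matrix = pair_probabilities_local(wt, model, params)
        mut_matrix = pair_probabilities_local(mut, model, params)
        wt_acc = accessibility_profile(wt, model, params)
        mut_acc = accessibility_profile(mut, model, params)
        report = build_impact_report(
            wt, spec, model, params,
            window_lengths=config.scan_window_lengths, step=config.scan_step,
            compute_pvalues=config.compute_pvalues,
        )
    else:
        dp_wt_seq, wt_matrix = read_ps_dotplot(config.wt_dotplot)
        dp_mut_seq, mut_matrix = read_ps_dotplot(config.mut_dotplot)
        if dp_wt_seq.residues != wt.residues:
            logger.warning("dot-plot WT sequence differs from FASTA input")
        if wt_matrix.n != mut_matrix.n:
            raise ValueError(
                f"dot-plot sizes differ: {wt_matrix.n} vs {mut_matrix.n}"
            )
        # accessibility from the matrices (global-mode identity pu = 1 - sum)
        def acc_from(mat):
            pu = np.clip(1.0 - mat.row_sums(), 0.0, 1.0)
            return AccessibilityProfile(
                n=mat.n, pu=pu, pu_u={1: pu.copy()}, params=params,
                model_id=mat.model_id,
            )
        wt_acc, mut_acc = acc_from(wt_matrix), acc_from(mut_matrix)
        scan = region_distance_scan(
            wt_matrix, mut_matrix, config.scan_window_lengths, config.scan_step
        )
        report = ImpactReport(
            relent=None, scan=scan, mutation=spec, params=params,
            model_id="dotplot-file",
        )

    diff = build_diff_result(wt_matrix, mut_matrix, wt_acc, mut_acc)

    files: list[Path] = []
    tsv_paths = write_tsv_outputs(diff, wt_acc, mut_acc, report, out_dir)
    files.extend(tsv_paths.values())

    # dot plots for interop (also what the dotplot-files backend consumes)
    files.append(write_ps_dotplot(wt_matrix, wt, out_dir / "wt_dotplot.ps"))
    files.append(write_ps_dotplot(mut_matrix, mut, out_dir / "mut_dotplot.ps"))

    if config.make_plots:
        spec_r = RenderSpec(
            formats=config.render.formats,
            dpi=config.render.dpi,
            tick_interval=config.render.tick_interval,
            mutation_marks=tuple(e.position for e in spec.edits),
            threshold=config.render.threshold,
            diff_floor=config.render.diff_floor,
        )
        stems = _figure_stems("mutfold")
        files += render_heatmap(
            wt_matrix.P, spec_r, out_dir / stems["wt"], title="WT pair probabilities"
        )
        files += render_heatmap(
            mut_matrix.P, spec_r, out_dir / stems["mut"],
            title=f"mutant ({spec.code()}) pair probabilities",
        )
        files += render_heatmap(
            diff.combined, spec_r, out_dir / stems["combined"],
            title="combined (WT upper / mutant lower)",
        )
        files += render_diff_heatmap(
            diff.delta, spec_r, out_dir / stems["diff"],
            title="pair probability delta (mutant - WT)",
        )
        files += render_heatmap(
            diff.weakened, spec_r, out_dir / stems["weakened"],
            title="weakened base pairs",
        )
        files += render_heatmap(
            diff.strengthened, spec_r, out_dir / stems["strengthened"],
            title="strengthened base pairs",
        )
        files += render_circular(
            diff.delta, spec_r, out_dir / stems["circular"],
            mutation_code=spec.code(), differential=True,
            title="differential circular plot",
        )
        files += render_arc_diagram(
            wt_matrix, mut_matrix, spec_r, out_dir / stems["arcs"],
            title="WT (top) vs mutant (bottom) arcs",
        )
        files += render_accessibility(
            wt_acc, mut_acc, diff.acc_delta, spec_r,
            out_dir / stems["accessibility"], title="accessibility (WT - mut)",
        )

    config_path = out_dir / "config.json"
    config_path.write_text(json.dumps(config.echo(), indent=2) + "\n")
    files.append(config_path)
    files.append(log_path)

    rel_files = sorted(str(p.relative_to(out_dir)) for p in files)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"files": rel_files}, indent=2) + "\n")

    bundle = out_dir / "results.zip"
    with zipfile.ZipFile(bundle, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.write(manifest_path, "manifest.json")
        for rel in rel_files:
            zf.write(out_dir / rel, rel)
    logger.info("bundle written: %s (%d files)", bundle, len(rel_files) + 1)

    return RunResult(
        out_dir=out_dir,
        files=[manifest_path] + [Path(out_dir / r) for r in rel_files],
        report=report,
        bundle_zip=bundle,
    )
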