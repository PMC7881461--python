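"""End-to-end orchestration: design -> simulate -> process -> call -> report.

A single top-level seed is fanned out deterministically to the stages
(design tagging, molecule sampling, read simulation, downsampling) so a
rerun with the same config is bit-identical at the count level, and each
stage can be reproduced in isolation from its recorded sub-seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calling import call_target
from .design import DesignConfig, design_panel
from .io import (
    load_fasta,
    load_variants_vcf,
    write_calls_vcf,
    write_counts_tsv,
    write_panel,
    call_to_dict,
)
from .quantify import pileup_counts
from .readproc import process_reads
from .simulate import (
    DilutionSeries,
    ErrorModel,
    SimScenario,
    simulate_amplicon_reads,
    simulate_scenario,
    write_fastq,
)

log = logging.getLogger("mippseq")

STAGES = ("design", "simulate", "process", "call", "report")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run."""

    reference: str
    targets: str  # VCF of target variant(s)
    out: str
    known: str | None = None  # VCF of germline variants to mask/exclude
    platform: str = "ion"
    seed: int = 0
    true_aaf: float = 0.05
    input_mass_ng: float = 50.0
    depth_per_amplicon: int = 400
    read_level: bool = True
    n_amplicons: int = 3
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"reference", "targets", "out"} - set(data)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    The manifest records the package version, the config, per-stage
    seeds, and input digests. Count-level outputs are bit-identical
    across reruns of the same config.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)

    for path, name in ((config.reference, "reference"), (config.targets, "targets")):
        if not Path(path).exists():
            raise StageError("design", FileNotFoundError(f"{name} file not found: {path}"))

    # --- design -----------------------------------------------------------
    try:
        refs = load_fasta(config.reference)
        targets = load_variants_vcf(config.targets)
        known = load_variants_vcf(config.known) if config.known else []
        if not targets:
            raise ValueError("no target variants in VCF")
        target = targets[0]
        ref_seq = refs[target.contig]
        dconf = DesignConfig(n_amplicons=config.n_amplicons)
        panel = design_panel(
            ref_seq,
            target,
            known_variants=[v for v in known if v.contig == target.contig],
            config=dconf,
            platform=config.platform,
            seed=stage_seed(config.seed, "design"),
        )
        write_panel(panel, outdir / "panel")
        log.info("designed %d amplicons", len(panel))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - deliberate stage boundary
        raise StageError("design", e) from e

    # --- simulate ---------------------------------------------------------
    try:
        sim_seed = stage_seed(config.seed, "simulate")
        if config.read_level:
            from .simulate import molecules_from_mass, sample_input_molecules

            rng = np.random.default_rng(sim_seed)
            copies = molecules_from_mass(config.input_mass_ng)
            alt, ref_c = sample_input_molecules(copies, config.true_aaf, rng)
            reads = []
            for amp in panel:
                reads.extend(
                    simulate_amplicon_reads(
                        amp, target, alt, ref_c, config.depth_per_amplicon,
                        ErrorModel(), rng,
                    )
                )
            write_fastq(reads, outdir / "reads.fastq.gz")
            log.info("simulated %d reads", len(reads))
        else:
            scenario = SimScenario(
                panel=panel,
                true_aaf=config.true_aaf,
                input_mass_ng=config.input_mass_ng,
                depth_per_amplicon=config.depth_per_amplicon,
                seed=sim_seed,
            )
            tables, _ = simulate_scenario(scenario)
    except Exception as e:
        raise StageError("simulate", e) from e

    # --- process ----------------------------------------------------------
    try:
        if config.read_level:
            aligned, stats = process_reads(reads, panel)
            log.info("processed reads: %s", stats)
            amp_by_id = {a.id: a for a in panel.amplicons}
            tables = {
                amp_id: pileup_counts(alns, amp_by_id[amp_id])
                for amp_id, alns in aligned.items()
            }
            (outdir / "demux_summary.json").write_text(json.dumps(stats))
    except Exception as e:
        raise StageError("process", e) from e

    # --- call -------------------------------------------------------------
    try:
        germline_sites = {v.span[0] for v in known}
        call = call_target(tables, panel, target, germline_sites=germline_sites)
        write_counts_tsv(tables, outdir / "counts.tsv")
        write_calls_vcf([call], outdir / "calls.vcf", {target.contig: len(ref_seq)})
        (outdir / "calls.json").write_text(json.dumps(call_to_dict(call), indent=2))
        log.info("verdict: %s (mean AAF %.4g)", call.verdict, call.mean_aaf)
    except Exception as e:
        raise StageError("call", e) from e

    # --- report -----------------------------------------------------------
    try:
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
            "inputs": {
                "reference": _digest(config.reference),
                "targets": _digest(config.targets),
            },
            "verdict": call.verdict,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as e:
        raise StageError("report", e) from e
    return outdir


def plot_series(report, path) -> None:
    """Sensitivity plot: measured vs expected AAF on log-log axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ok = report.measured > 0
    ax.loglog(report.true_aafs[ok], report.measured[ok], "ko-", label="pooled mean AAF")
    for amp_id, vals in report.per_amplicon.items():
        m = ~np.isnan(vals) & (vals > 0)
        ax.loglog(report.true_aafs[m], vals[m], ".", alpha=0.5, label=amp_id)
    lims = [report.true_aafs.min(), report.true_aafs.max()]
    ax.loglog(lims, lims, "--", color="grey", lw=1, label="identity")
    ax.set_xlabel("expected AAF")
    ax.set_ylabel("measured AAF")
    ax.set_title(f"$R^2$ = {report.r_squared:.4f}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
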