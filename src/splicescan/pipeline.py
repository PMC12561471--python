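"""Stage orchestration: parse → events → scan → target → psi/diff → report.

A single YAML/dict config drives the run; every analysis threshold has an
explicit default echoed into the run manifest (JSON) together with input
checksums and the output inventory, so every number in every output table
is regenerable from manifest + inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import as_events, event_targeting, genome_model, motif_scan, splice_quant
from .synthetic_data import SimulationConfig, write_simulation

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "motif": motif_scan.PRIMARY_MOTIF_RNA,
    "orientation_mode": "as_printed",
    "window_bp": event_targeting.DEFAULT_WINDOW_BP,
    "min_reads": splice_quant.DEFAULT_MIN_READS,
    "dpsi_min": splice_quant.DEFAULT_DPSI_MIN,
    "q_max": splice_quant.DEFAULT_Q_MAX,
    "max_distance": 200,
    "sense_only": True,
    "diff_method": "betabinom",
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return {**DEFAULT_CONFIG, **user}


def run_all(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run every stage; returns the run manifest (also written to disk)."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs: files or simulation block
    if "simulation" in config:
        sim_cfg = SimulationConfig(
            seed=int(config["seed"]), **config["simulation"]
        )
        simdir = outdir / "sim"
        genome, genes, truth, counts = write_simulation(sim_cfg, simdir)
        fasta_path = simdir / "genome.fa"
        gtf_path = simdir / "annotation.gtf"
        counts_path = simdir / "junction_counts.tsv"
        conditions = list(sim_cfg.conditions)
    else:
        for key in ("fasta", "gtf"):
            if key not in config:
                raise PipelineError(
                    f"parse stage: config lacks {key!r} and no simulation block"
                )
        fasta_path = Path(config["fasta"])
        gtf_path = Path(config["gtf"])
        if not fasta_path.exists():
            raise PipelineError(f"parse stage: missing FASTA {fasta_path}")
        if not gtf_path.exists():
            raise PipelineError(f"parse stage: missing GTF {gtf_path}")
        genome = genome_model.read_fasta(fasta_path)
        genes = genome_model.read_gtf(gtf_path)
        counts_path = Path(config["counts"]) if "counts" in config else None
        counts = (
            splice_quant.read_counts_tsv(counts_path) if counts_path else None
        )
        conditions = config.get("conditions")
        if "simulation" not in config and counts is not None and conditions is None:
            conditions = sorted(counts.condition.unique())

    if "simulation" in config:
        genome = genome_model.read_fasta(fasta_path)  # exercise the file path
        genes = genome_model.read_gtf(gtf_path)

    # --- parse report
    parse_report = genome_model.model_summary(genome, genes)
    (outdir / "model_report.json").write_text(
        json.dumps(parse_report, indent=2, sort_keys=True)
    )

    # --- events
    events = as_events.enumerate_all_events(genes)
    as_events.write_events_tsv(events, outdir / "events.tsv")
    event_counts = as_events.count_events_by_type(events)
    pd.DataFrame(
        [{"event_type": t, "count": c} for t, c in event_counts.items()]
    ).to_csv(outdir / "event_counts.tsv", sep="\t", index=False)

    # --- scan
    motif = motif_scan.build_query(config["motif"], config["orientation_mode"])
    hits = motif_scan.scan(genome, motif)
    motif_scan.write_hits_bed(hits, outdir / "hits.bed")
    annotations = motif_scan.annotate_hits(hits, genes)
    hit_summary = motif_scan.summarize_hits(annotations)
    (outdir / "hit_summary.json").write_text(
        json.dumps(hit_summary, indent=2, sort_keys=True)
    )
    density = motif_scan.distance_density(annotations, config["max_distance"])
    density.to_csv(outdir / "site_distance_density.tsv", sep="\t", index=False)

    # --- targeting
    tconfig = event_targeting.TargetingConfig(
        window_bp=int(config["window_bp"]), sense_only=bool(config["sense_only"])
    )
    flags, summary = event_targeting.targeted_events(events, hits, tconfig)
    flags.to_csv(outdir / "event_targeting_flags.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "targeting.tsv", sep="\t", index=False)
    profile = event_targeting.event_site_distance_profile(
        events, hits, config["max_distance"], sense_only=bool(config["sense_only"])
    )
    profile.to_csv(outdir / "event_site_profile.tsv", sep="\t", index=False)

    # --- quantification (only when counts exist)
    tallies = None
    if counts is not None:
        psi = splice_quant.psi_table(counts, min_reads=int(config["min_reads"]))
        psi.to_csv(outdir / "psi.tsv", sep="\t", index=False, float_format="%.6g")
        if conditions and len(conditions) >= 2:
            cond_a, cond_b = conditions[0], conditions[1]
            results, tallies = splice_quant.differential_inclusion(
                counts, cond_a, cond_b,
                dpsi_min=float(config["dpsi_min"]),
                q_max=float(config["q_max"]),
                min_reads=int(config["min_reads"]),
                method=str(config["diff_method"]),
            )
            results.to_csv(
                outdir / "differential.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            tallies.to_csv(outdir / "differential_tally.tsv", sep="\t", index=False)
            expressed = {
                c: splice_quant.count_expressed_events(
                    psi, c, min_reads=int(config["min_reads"])
                )
                for c in (cond_a, cond_b)
            }
            (outdir / "expressed_events.json").write_text(
                json.dumps(expressed, indent=2, sort_keys=True)
            )

    # --- manifest
    def _rel(p: Path) -> str:
        try:
            return str(Path(p).relative_to(outdir))
        except ValueError:
            return str(p)

    inputs = {
        "fasta": {"path": _rel(fasta_path), "sha256": _sha256(Path(fasta_path))},
        "gtf": {"path": _rel(gtf_path), "sha256": _sha256(Path(gtf_path))},
    }
    if counts is not None and counts_path is not None:
        inputs["counts"] = {
            "path": _rel(counts_path), "sha256": _sha256(Path(counts_path))
        }
    outputs = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": {
            k: v for k, v in sorted(config.items()) if k != "simulation"
        },
        "simulation": config.get("simulation"),
        "inputs": inputs,
        "outputs": outputs,
        "stage_versions": {"splicescan": _package_version()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__


def render_report(outdir: str | Path, plots: bool = True) -> Path:
    """Write report.md (plus PNG plots) from the stage outputs present.

    Missing stages are listed rather than fatal.
    """
    outdir = Path(outdir)
    lines = ["# splicescan run report", ""]
    missing = []

    def _table(df: pd.DataFrame) -> list[str]:
        if df.empty:
            return ["(no rows)", ""]
        header = "| " + " | ".join(df.columns) + " |"
        sep = "| " + " | ".join("---" for _ in df.columns) + " |"
        body = [
            "| " + " | ".join(str(v) for v in row) + " |"
            for row in df.itertuples(index=False)
        ]
        return [header, sep, *body, ""]

    ec_path = outdir / "event_counts.tsv"
    lines.append("## Alternative-splicing event counts")
    if ec_path.exists():
        ec = pd.read_csv(ec_path, sep="\t")
        if ec["count"].sum() == 0:
            lines += ["No events enumerated.", ""]
        else:
            lines += _table(ec)
        if plots and ec["count"].sum() > 0:
            _bar_plot(ec, outdir / "event_counts.png")
            lines += ["![event counts](event_counts.png)", ""]
    else:
        missing.append("event_counts.tsv")

    t_path = outdir / "targeting.tsv"
    lines.append("## Motif-targeted proportions per event class")
    if t_path.exists():
        lines += _table(pd.read_csv(t_path, sep="\t"))
    else:
        missing.append("targeting.tsv")

    d_path = outdir / "site_distance_density.tsv"
    lines.append("## Motif-to-splice-site distance density")
    if d_path.exists():
        dens = pd.read_csv(d_path, sep="\t")
        total = int(dens.donor_count.sum() + dens.acceptor_count.sum())
        lines += [f"{total} in-window hit annotations.", ""]
        if plots and total:
            _density_plot(dens, outdir / "site_distance_density.png")
            lines += ["![distance density](site_distance_density.png)", ""]
    else:
        missing.append("site_distance_density.tsv")

    dt_path = outdir / "differential_tally.tsv"
    lines.append("## Differential inclusion (up/down tallies)")
    if dt_path.exists():
        lines += _table(pd.read_csv(dt_path, sep="\t"))
    else:
        lines += ["No count table supplied; differential stage not run.", ""]

    if missing:
        lines.append("## Missing stage outputs")
        lines += [f"- {m}" for m in missing]
        lines.append("")

    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report


def _bar_plot(event_counts: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(event_counts.event_type, event_counts["count"], color="#4878a8")
    ax.set_ylabel("events")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _density_plot(density: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(density.bin_start, density.donor_count, label="donor", lw=0.8)
    ax.plot(density.bin_start, density.acceptor_count, label="acceptor", lw=0.8)
    ax.set_xlabel("signed distance to splice site (bp)")
    ax.set_ylabel("hits")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
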