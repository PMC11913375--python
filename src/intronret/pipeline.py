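"""End-to-end orchestration: simulate -> count -> IRS -> classify -> motifs -> lengths.

One :func:`run_pipeline` call executes the stages in dependency order,
writes every stage table as TSV plus a machine-readable run manifest
(parameters, input checksums, seed, per-stage row counts) and a short
human-readable summary.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotation, classify, features, lengths, retention, simulate
from ._util import read_tsv, sha256_file, write_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` holds a :class:`~intronret.simulate.SimConfig` (the
    run generates its own data) or ``genome``/``gtf``/``sample_sheet`` point
    at existing inputs.  Parameter defaults equal the module defaults.
    """

    outdir: str = "intronret_run"
    seed: int = 0
    simulate: simulate.SimConfig | None = None
    genome: str | None = None
    gtf: str | None = None
    sample_sheet: str | None = None  # TSV: sample_id, condition, replicate, path
    min_anchor: int = 5
    min_total: int = 10
    pseudocount: float = 1.0
    strong_cut: float = 2.0
    var_mode: str = "per_intron"
    e5: int = 3
    i5: int = 6
    i3: int = 6
    e3: int = 1
    length_edges: tuple[int | None, ...] = lengths.DEFAULT_EDGES
    scan_10nt: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["signature_proportions"] = dict(self.simulate.signature_proportions)
            d["simulate"] = sim
        d["length_edges"] = list(self.length_edges)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            for key in ("exons_per_gene", "exon_length"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "intron_length_mixture" in sim:
                sim["intron_length_mixture"] = tuple(
                    tuple(row) for row in sim["intron_length_mixture"]
                )
            if sim.get("length_multiplier_kd") is not None:
                sim["length_multiplier_kd"] = tuple(
                    tuple(row) for row in sim["length_multiplier_kd"]
                )
            sim = simulate.SimConfig(**sim)
        if "length_edges" in d:
            d["length_edges"] = tuple(d["length_edges"])
        return cls(simulate=sim, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@dataclass
class RunResult:
    outdir: Path
    summary: dict[str, Any]
    manifest: dict[str, Any]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write TSVs, manifest and summary to outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in config.to_dict().items()
            if k not in {"outdir", "simulate", "genome", "gtf", "sample_sheet"}
        },
        "inputs": {},
        "stages": {},
    }

    # --- stage: inputs (simulate or load) --------------------------------
    if config.simulate is not None:
        sim = _stage("simulate")(simulate.simulate_genome)(config.simulate, seed=config.seed)
        fasta = sim.write_fasta(out / "genome.fa")
        gtf = sim.write_gtf(out / "annotation.gtf")
        sim.write_truth(out / "truth.tsv")
        reads = _stage("simulate")(simulate.simulate_alignments)(
            sim, out / "alignments", seed=config.seed + 1
        )
        write_tsv(reads.realized_counts, out / "realized_counts.tsv")
        sheet = reads.sample_sheet
        # manifest paths relative to outdir so reruns are comparable
        sheet_for_disk = sheet.copy()
        sheet_for_disk["path"] = [str(Path(p).relative_to(out)) for p in sheet["path"]]
        write_tsv(sheet_for_disk, out / "sample_sheet.tsv")
        logger.info("simulate: %d introns, %d samples", len(sim.introns), len(sheet))
        manifest["stages"]["simulate"] = {
            "n_introns": len(sim.introns),
            "n_samples": int(len(sheet)),
        }
    else:
        for name, path in (("genome", config.genome), ("gtf", config.gtf),
                           ("sample_sheet", config.sample_sheet)):
            if path is None:
                raise PipelineError(f"stage 'inputs' failed: missing {name}")
        fasta, gtf = Path(config.genome), Path(config.gtf)
        sheet = read_tsv(config.sample_sheet)

    for p in (fasta, gtf):
        manifest["inputs"][Path(p).name] = sha256_file(p)

    # --- stage: count ----------------------------------------------------
    introns = _stage("count")(annotation.extract_introns)(gtf)
    counts = _stage("count")(annotation.count_junctions)(
        sheet, introns, min_anchor=config.min_anchor
    )
    write_tsv(counts, out / "junction_counts.tsv")
    logger.info("count: %d introns x %d samples", len(introns), len(sheet))
    manifest["stages"]["count"] = {"n_rows": int(len(counts))}

    # --- stage: filter + irs --------------------------------------------
    kept, dropped = annotation.filter_low_coverage(counts, min_total=config.min_total)
    irs = _stage("irs")(retention.compute_irs)(
        counts[counts["intron_id"].isin(kept)], pseudocount=config.pseudocount
    )
    write_tsv(irs, out / "irs_per_sample.tsv")
    summaries = _stage("irs")(retention.summarize_conditions)(irs, var_mode=config.var_mode)
    write_tsv(summaries, out / "irs_summary.tsv")
    logger.info("irs: %d kept, %d low-coverage introns", len(kept), len(dropped))
    manifest["stages"]["irs"] = {"n_kept": len(kept), "n_low_coverage": len(dropped)}

    # --- stage: classify -------------------------------------------------
    result = _stage("classify")(classify.classify_introns)(
        summaries, strong_cut=config.strong_cut
    )
    cats = result.table
    low = pd.DataFrame(
        {
            "intron_id": sorted(dropped),
            "category": classify.IntronCategory.LOW_COVERAGE.value,
            "z_score": float("nan"),
            "irs_diff": float("nan"),
            "high_confidence_z": False,
        }
    )
    cats_full = pd.concat([cats, low], ignore_index=True).sort_values("intron_id")
    write_tsv(cats_full, out / "intron_categories.tsv")
    counts_per_cat = result.counts()
    counts_per_cat["LOW_COVERAGE"] = len(dropped)
    logger.info("classify: %s (irs_diff cutoff %.4g)", counts_per_cat, result.irs_diff_cutoff)
    manifest["stages"]["classify"] = {
        "categories": counts_per_cat,
        "q1_threshold": result.q1_threshold,
        "q3_threshold": result.q3_threshold,
        "irs_diff_cutoff": result.irs_diff_cutoff,
    }

    # --- stage: motifs ---------------------------------------------------
    windows = _stage("motifs")(features.extract_site_windows)(
        str(fasta), introns, e5=config.e5, i5=config.i5, i3=config.i3, e3=config.e3
    )
    write_tsv(windows, out / "site_windows.tsv")
    merged = windows.merge(cats, on="intron_id", how="inner")
    hi = merged[merged["high_confidence_z"]]
    un = merged[merged["category"] == classify.IntronCategory.UNAFFECTED.value]
    pwm_sets = {"all": merged, "strongly_affected": hi, "unaffected": un}
    for name, sub in pwm_sets.items():
        if sub.empty:
            logger.warning("motifs: set %s empty; PWM skipped", name)
            continue
        for side in ("five_prime_window", "three_prime_window"):
            pm = features.build_matrix(sub[side].tolist())
            tag = "5ss" if side.startswith("five") else "3ss"
            write_tsv(pm.to_frame(), out / f"pwm_{name}_{tag}.tsv")
    if not hi.empty and not un.empty:
        for side, tag in (("five_prime_window", "5ss"), ("three_prime_window", "3ss")):
            dm = features.diff_matrix(
                features.build_matrix(hi[side].tolist()),
                features.build_matrix(un[side].tolist()),
            )
            write_tsv(dm, out / f"difflogo_{tag}.tsv")
        fisher_rows = []
        # the exonic positions of interest: -3/-2/-1 of the 5'SS (A, A, G)
        # and +1 of the 3' exon (G)
        for pos, base in ((config.e5 - 3, "A"), (config.e5 - 2, "A"), (config.e5 - 1, "G")):
            orr, p, table = features.position_fisher(
                un["five_prime_window"].tolist(), hi["five_prime_window"].tolist(), pos, base
            )
            fisher_rows.append(
                {"window": "5ss", "position": pos, "base": base,
                 "odds_ratio": orr, "p_value": p,
                 "a_in": table[0][0], "a_out": table[0][1],
                 "b_in": table[1][0], "b_out": table[1][1]}
            )
        orr, p, table = features.position_fisher(
            un["three_prime_window"].tolist(), hi["three_prime_window"].tolist(),
            config.i3, "G",
        )
        fisher_rows.append(
            {"window": "3ss", "position": config.i3, "base": "G",
             "odds_ratio": orr, "p_value": p,
             "a_in": table[0][0], "a_out": table[0][1],
             "b_in": table[1][0], "b_out": table[1][1]}
        )
        write_tsv(pd.DataFrame(fisher_rows), out / "fisher_positions.tsv")
    sig = windows[["intron_id", "last3_exon", "first1_exon3", "signature_group"]]
    write_tsv(sig, out / "signature_groups.tsv")
    by_group = {
        g: sub.merge(summaries, on="intron_id")["irs_diff"].dropna().to_numpy()
        for g, sub in sig.groupby("signature_group")
    }
    ecdf = features.group_irs_curves(by_group)
    write_tsv(ecdf, out / "group_ecdf.tsv")
    group_counts = sig["signature_group"].value_counts().to_dict()
    logger.info("motifs: signature groups %s", group_counts)
    manifest["stages"]["motifs"] = {"signature_groups": {k: int(v) for k, v in group_counts.items()}}

    # --- stage: lengths --------------------------------------------------
    bins = lengths.make_bins(config.length_edges)
    if config.scan_10nt:
        bins = lengths.ten_nt_bins()
    length_df = pd.DataFrame(
        {"intron_id": [i.intron_id for i in introns], "length": [i.length for i in introns]}
    )
    assignments = _stage("lengths")(lengths.bin_by_length)(length_df, bins)
    write_tsv(assignments, out / "length_bins.tsv")
    profiles, len_ecdf, composition = _stage("lengths")(lengths.length_defect_profile)(
        summaries, assignments, cats_full
    )
    write_tsv(profiles, out / "length_profiles.tsv")
    write_tsv(len_ecdf, out / "length_ecdf.tsv")
    if composition is not None:
        write_tsv(composition, out / "length_composition.tsv")
    diff_by_bin = {
        label: sub.merge(summaries, on="intron_id")["irs_diff"].dropna().to_numpy()
        for label, sub in assignments.groupby("bin", sort=False)
    }
    diff_by_bin = {k: v for k, v in diff_by_bin.items() if len(v) > 0}
    if len(diff_by_bin) >= 2:
        wmat = _stage("lengths")(lengths.compare_bins)(diff_by_bin)
        wmat.index.name = "bin"
        write_tsv(wmat.reset_index(), out / "wilcoxon_matrix.tsv")
    bin_medians = {
        r["bin"]: r["irs_diff_median"] for _, r in profiles.iterrows()
    }
    logger.info("lengths: per-bin median IRSdiff %s", bin_medians)
    manifest["stages"]["lengths"] = {
        "bins": {k: int(v) for k, v in assignments["bin"].value_counts().items()}
    }

    # --- manifest + summary ---------------------------------------------
    summary = {
        "categories": counts_per_cat,
        "signature_groups": {k: int(v) for k, v in group_counts.items()},
        "bin_median_irs_diff": {k: float(v) for k, v in bin_medians.items()},
        "irs_diff_cutoff": result.irs_diff_cutoff,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    lines = ["pipeline summary", "================"]
    lines.append("category counts:")
    lines += [f"  {k}: {v}" for k, v in counts_per_cat.items()]
    lines.append("signature group counts:")
    lines += [f"  {k}: {v}" for k, v in sorted(group_counts.items())]
    lines.append("per-bin median IRSdiff:")
    lines += [f"  {k}: {v:.4g}" for k, v in bin_medians.items()]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return RunResult(outdir=out, summary=summary, manifest=manifest)
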