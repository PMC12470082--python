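"""End-to-end pipeline: configuration, orchestration, report bundle.

A run is described by a YAML config with exactly one data source — a
``simulate`` block (erosion simulator) or an ``input`` block (FASTA on
disk) — plus the clade partition, the calibration anchor, and the
analysis thresholds. Every stage writes its artifact into the output
directory; a failure leaves a ``FAILED`` marker naming the stage.

Outputs are deterministic given config + seed (no timestamps), so two
identical runs produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotate import (CladePartition, classify_positions, clade_markers,
                       substitution_spectrum, tile_dinucleotides,
                       variability_stats)
from .recode import recode_cpg, write_recoded_fasta
from .seqio import Msa, SequenceRecord, align_or_load, read_fasta, write_fasta
from .simulate import (CALIBRATION_PAIR, CALIBRATION_TIME_MA, ErosionParams,
                       generate_study_like_dataset, study_partition)
from .trees import (calibrate, p_distance, percent_identity, rf_distance,
                    upgma, write_newick)

log = logging.getLogger("cpgphylo")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message carries the key path."""


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    simulate: dict[str, Any] | None
    input: dict[str, Any] | None
    locus_order: list[str]
    clade_partition: CladePartition
    calibration_pair: tuple[str, str]
    calibration_time_ma: float
    cgi: dict[str, float]
    tiling: str

    def effective_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "simulate": self.simulate,
            "input": self.input,
            "locus_order": self.locus_order,
            "clade_partition": {
                "name_a": self.clade_partition.name_a,
                "members_a": sorted(self.clade_partition.members_a),
                "name_b": self.clade_partition.name_b,
                "members_b": sorted(self.clade_partition.members_b),
            },
            "calibration": {"pair": list(self.calibration_pair),
                            "time_ma": self.calibration_time_ma},
            "cgi": self.cgi,
            "tiling": self.tiling,
        }


_TOP_KEYS = {"seed", "output_dir", "simulate", "input", "locus_order",
             "clade_partition", "calibration", "cgi", "tiling"}
_SIM_KEYS = {"mu", "lambda_cpg", "kappa", "cpg_fraction", "locus_lengths", "n_taxa"}
_INPUT_KEYS = {"aligned_fasta", "fasta", "align"}
_CGI_DEFAULTS = {"min_gc": 0.5, "min_obs_exp": 0.6, "min_len": 200}


def _members(raw: Any, path: str) -> frozenset[str]:
    if not isinstance(raw, list) or not raw:
        raise ConfigError(f"{path}: expected a non-empty list of species")
    if len(set(raw)) != len(raw):
        dupes = sorted({x for x in raw if raw.count(x) > 1})
        raise ConfigError(f"{path}: duplicate species {dupes}")
    return frozenset(raw)


def validate_config_dict(raw: Mapping[str, Any]) -> PipelineConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    sim = raw.get("simulate")
    inp = raw.get("input")
    if (sim is None) == (inp is None):
        raise ConfigError("exactly one of 'simulate' / 'input' must be present")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed: expected an integer")

    if sim is not None:
        if not isinstance(sim, dict):
            raise ConfigError("simulate: expected a mapping")
        unknown = set(sim) - _SIM_KEYS
        if unknown:
            raise ConfigError(f"simulate: unknown keys {sorted(unknown)}")
        defaults = ErosionParams(seed=seed)
        sim = {
            "mu": float(sim.get("mu", defaults.mu)),
            "lambda_cpg": float(sim.get("lambda_cpg", defaults.lambda_cpg)),
            "kappa": float(sim.get("kappa", defaults.kappa)),
            "cpg_fraction": float(sim.get("cpg_fraction", defaults.cpg_fraction)),
            "locus_lengths": [int(x) for x in sim.get("locus_lengths", [1700, 1600, 1700])],
            "n_taxa": int(sim.get("n_taxa", 12)),
        }
    if inp is not None:
        if not isinstance(inp, dict):
            raise ConfigError("input: expected a mapping")
        unknown = set(inp) - _INPUT_KEYS
        if unknown:
            raise ConfigError(f"input: unknown keys {sorted(unknown)}")
        if ("aligned_fasta" in inp) == ("fasta" in inp):
            raise ConfigError("input: exactly one of 'aligned_fasta' / 'fasta'")

    part_raw = raw.get("clade_partition")
    if part_raw is None:
        if sim is None or sim["n_taxa"] != 12:
            raise ConfigError("clade_partition: required for this data source")
        partition = study_partition()
    else:
        unknown = set(part_raw) - {"name_a", "members_a", "name_b", "members_b"}
        if unknown:
            raise ConfigError(f"clade_partition: unknown keys {sorted(unknown)}")
        try:
            partition = CladePartition(
                name_a=str(part_raw.get("name_a", "clade_a")),
                members_a=_members(part_raw.get("members_a"), "clade_partition.members_a"),
                name_b=str(part_raw.get("name_b", "clade_b")),
                members_b=_members(part_raw.get("members_b"), "clade_partition.members_b"),
            )
        except ValueError as exc:
            raise ConfigError(f"clade_partition: {exc}") from exc

    cal = raw.get("calibration") or {}
    unknown = set(cal) - {"pair", "time_ma"}
    if unknown:
        raise ConfigError(f"calibration: unknown keys {sorted(unknown)}")
    pair = tuple(cal.get("pair", list(CALIBRATION_PAIR)))
    if len(pair) != 2 or pair[0] == pair[1]:
        raise ConfigError("calibration.pair: expected two distinct species")
    time_ma = float(cal.get("time_ma", CALIBRATION_TIME_MA))
    if time_ma <= 0:
        raise ConfigError("calibration.time_ma: must be positive")
    known = partition.members_a | partition.members_b
    missing = set(pair) - known
    if missing:
        raise ConfigError(
            f"calibration.pair: species {sorted(missing)} not in the clade partition"
        )

    cgi_raw = raw.get("cgi") or {}
    unknown = set(cgi_raw) - set(_CGI_DEFAULTS)
    if unknown:
        raise ConfigError(f"cgi: unknown keys {sorted(unknown)}")
    cgi = {**_CGI_DEFAULTS, **{k: float(v) for k, v in cgi_raw.items()}}
    cgi["min_len"] = int(cgi["min_len"])

    tiling = raw.get("tiling", "paired")
    if tiling != "paired":
        raise ConfigError(f"tiling: only 'paired' is supported, got {tiling!r}")

    cfg = PipelineConfig(
        seed=seed,
        output_dir=Path(raw.get("output_dir", "cpgphylo_out")),
        simulate=sim, input=inp,
        locus_order=list(raw.get("locus_order", ["OCT4", "SOX2", "hTERT"])),
        clade_partition=partition,
        calibration_pair=(str(pair[0]), str(pair[1])),
        calibration_time_ma=time_ma,
        cgi=cgi, tiling=tiling,
    )
    for key, value in sorted(cfg.effective_dict().items()):
        if key not in raw:
            log.info("config default applied: %s = %r", key, value)
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return validate_config_dict(raw)


def emit_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.effective_dict(), sort_keys=True))


def _config_hash(cfg: PipelineConfig) -> str:
    # output location does not alter what is computed
    eff = {k: v for k, v in cfg.effective_dict().items() if k != "output_dir"}
    return hashlib.sha256(json.dumps(eff, sort_keys=True).encode()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle into cfg.output_dir.

    Returns a dict of in-memory results (stats, trees, rf distances, paths).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    results: dict[str, Any] = {"output_dir": str(out)}
    try:
        # -- data ----------------------------------------------------------
        stage = "data"
        dataset = None
        if cfg.simulate is not None:
            sim = cfg.simulate
            params = ErosionParams(mu=sim["mu"], lambda_cpg=sim["lambda_cpg"],
                                   kappa=sim["kappa"],
                                   cpg_fraction=sim["cpg_fraction"],
                                   seed=cfg.seed)
            dataset = generate_study_like_dataset(
                params, n_taxa=sim["n_taxa"],
                two_clades=cfg.clade_partition if sim["n_taxa"] != 12 else None,
                locus_lengths=sim["locus_lengths"],
                locus_names=cfg.locus_order[: len(sim["locus_lengths"])],
            )
            msa = dataset.msa
            write_fasta(dataset.sim.sequences, out / "concatenated.fasta")
            (out / "events.tsv").write_text(dataset.sim.events_tsv())
            write_newick(dataset.tree, out / "tree_truth.nwk")
        else:
            inp = cfg.input
            if "aligned_fasta" in inp:
                msa = align_or_load(path=inp["aligned_fasta"], mode="preloaded")
            else:
                recs = read_fasta(inp["fasta"], allow_gaps=False)
                msa = align_or_load(records=recs, mode="external")
            write_fasta([SequenceRecord(id=sid, seq=msa.degapped(sid))
                         for sid in msa.ids], out / "concatenated.fasta")
        missing = (set(cfg.calibration_pair) | cfg.clade_partition.members_a
                   | cfg.clade_partition.members_b) - set(msa.ids)
        if missing:
            raise ConfigError(f"species in config but not in data: {sorted(missing)}")
        write_fasta([SequenceRecord(id=sid, seq=row)
                     for sid, row in zip(msa.ids, msa.rows)],
                    out / "alignment.fasta")

        # -- annotation ----------------------------------------------------
        stage = "annotate"
        table = classify_positions(tile_dinucleotides(msa), msa)
        (out / "positions.tsv").write_text(table.to_tsv())
        stats = variability_stats(table, msa)
        (out / "variability.txt").write_text(stats.report())
        spectrum = substitution_spectrum(table)
        (out / "spectrum.tsv").write_text(spectrum.to_tsv())
        markers_cpg = clade_markers(table, cfg.clade_partition, mode="cpg")
        markers_snv = clade_markers(table, cfg.clade_partition, mode="snv")
        (out / "clade_markers.tsv").write_text(
            "mode\tindex\n"
            + "".join(f"cpg\t{i}\n" for i in markers_cpg)
            + "".join(f"snv\t{i}\n" for i in markers_snv)
        )
        results.update(stats=stats, spectrum=spectrum,
                       markers_cpg=markers_cpg, markers_snv=markers_snv)

        # -- recoding ------------------------------------------------------
        stage = "recode"
        recoded = recode_cpg(table)
        write_recoded_fasta(recoded, out / "recoded.fasta")
        (out / "recoded.tsv").write_text(recoded.to_tsv())
        results["recoded"] = recoded

        # -- distances and trees -------------------------------------------
        stage = "trees"
        pim = percent_identity(msa)
        (out / "percent_identity.tsv").write_text(pim.to_tsv())
        dm_all = p_distance(msa, count_indels=True)
        dm_cpg = p_distance(recoded)
        (out / "distance_all.tsv").write_text(dm_all.to_tsv())
        (out / "distance_cpg.tsv").write_text(dm_cpg.to_tsv())
        tree_all = calibrate(upgma(dm_all), cfg.calibration_pair,
                             cfg.calibration_time_ma)
        tree_cpg = calibrate(upgma(dm_cpg), cfg.calibration_pair,
                             cfg.calibration_time_ma)
        write_newick(tree_all, out / "tree_all_changes.nwk")
        write_newick(tree_cpg, out / "tree_cpg_only.nwk")
        rf_between = rf_distance(tree_all, tree_cpg)
        results.update(pim=pim, tree_all=tree_all, tree_cpg=tree_cpg,
                       rf_between=rf_between)
        if dataset is not None:
            results["truth"] = dataset.truth
            results["rf_all_vs_truth"] = rf_distance(tree_all, dataset.tree)
            results["rf_cpg_vs_truth"] = rf_distance(tree_cpg, dataset.tree)

        # -- report --------------------------------------------------------
        stage = "report"
        summary = [
            stats.report(),
            "substitution spectrum (top bins):",
            *(f"  CG->{alt}: {n}" for alt, n in spectrum.sorted_items()[:6]),
            f"clade-distinguishing CpG positions: {len(markers_cpg)}",
            f"clade-distinguishing non-CpG SNV columns: {len(markers_snv)}",
            f"RF distance, all-changes vs CpG-only tree: {rf_between}",
        ]
        if dataset is not None:
            summary += [
                f"RF distance, CpG-only tree vs truth: {results['rf_cpg_vs_truth']}",
                f"RF distance, all-changes tree vs truth: {results['rf_all_vs_truth']}",
            ]
        (out / "summary.txt").write_text("\n".join(summary) + "\n")
        manifest = {
            "config_hash": _config_hash(cfg),
            "config": cfg.effective_dict(),
            "cpgphylo_version": __version__,
            "outputs": sorted(p.name for p in out.iterdir()
                              if p.name not in ("manifest.json",)),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
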