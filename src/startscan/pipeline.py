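"""End-to-end orchestration: catalog → conservation → enrichment (→ structure).

A run is a pure function of (config, input files): every machine-readable
output is deterministic and byte-identical across reruns, and each
intermediate table is written to disk so any stage can be re-run or
inspected in isolation. Logging (timestamped, stage-scoped, with
record-count deltas after every filter) goes to the standard ``logging``
machinery, never into the machine-readable outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    DomainWindow,
    MutationClass,
    counts_to_frame,
    dedupe_patients,
    filter_catalog,
    ks_uniformity_test,
    per_residue_counts,
    read_catalog,
    write_catalog,
)
from .conservation import (
    DEFAULT_SIMILARITY_GROUPS,
    ColumnClass,
    annotate_mutations,
    classify_columns,
    consensus_logo,
    conserved_positions,
    map_columns_to_reference,
    read_alignment,
)
from .enrichment import EnrichmentInput, chi_square_test
from .structure import (
    diff_networks,
    interaction_network,
    interactions_to_frame,
    read_structure,
)

logger = logging.getLogger(__name__)


@dataclass
class ParalogConfig:
    """Inputs for one paralog (one domain window + its data files)."""

    name: str
    window: DomainWindow
    catalog_path: str
    alignment_path: str
    ref_start: int
    catalog_format: str = "internal"
    reference_id: Optional[str] = None
    wt_structure: Optional[str] = None
    mut_structures: dict[str, str] = field(default_factory=dict)
    network_residues: list[int] = field(default_factory=list)


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run."""

    paralogs: list[ParalogConfig]
    out_dir: str
    threshold: float = 0.98
    similarity_groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS
    cutoff: float = 4.0
    alpha: float = 0.05
    seed: int = 0
    dedupe_key: str = "patient_change"
    pool_physicochemical: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        paralogs = []
        for p in raw.get("paralogs", []):
            window = DomainWindow(p["name"], int(p["window"]["start"]), int(p["window"]["end"]))
            paralogs.append(
                ParalogConfig(
                    name=p["name"],
                    window=window,
                    catalog_path=p["catalog"],
                    alignment_path=p["alignment"],
                    ref_start=int(p.get("ref_start", window.start)),
                    catalog_format=p.get("catalog_format", "internal"),
                    reference_id=p.get("reference_id"),
                    wt_structure=p.get("wt_structure"),
                    mut_structures=dict(p.get("mut_structures", {})),
                    network_residues=list(p.get("network_residues", [])),
                )
            )
        glob = raw.get("global", {})
        return cls(
            paralogs=paralogs,
            out_dir=raw.get("out_dir", glob.get("out_dir", "startscan_out")),
            threshold=float(glob.get("threshold", 0.98)),
            similarity_groups=tuple(glob.get("similarity_groups", DEFAULT_SIMILARITY_GROUPS)),
            cutoff=float(glob.get("cutoff", 4.0)),
            alpha=float(glob.get("alpha", 0.05)),
            seed=int(glob.get("seed", 0)),
            dedupe_key=glob.get("dedupe_key", "patient_change"),
            pool_physicochemical=bool(glob.get("pool_physicochemical", False)),
        )

    def validate(self) -> None:
        if not self.paralogs:
            raise ValueError("config lists no paralogs")
        for p in self.paralogs:
            for path in filter(None, [p.catalog_path, p.alignment_path, p.wt_structure]):
                if not Path(path).exists():
                    raise FileNotFoundError(f"[{p.name}] input not found: {path}")
            for path in p.mut_structures.values():
                if not Path(path).exists():
                    raise FileNotFoundError(f"[{p.name}] input not found: {path}")


def export_lollipop(
    annotated: pd.DataFrame, paralog: str
) -> pd.DataFrame:
    """Plot-ready lollipop table (paralog, position, count, class).

    Keeps every position with at least one mutation plus every conserved
    position (identical or physicochemical class), so the domain's
    conservation architecture is visible even where counts are zero.
    """
    keep = (annotated["count"] > 0) | annotated["class"].isin(
        [ColumnClass.IDENTICAL.value, ColumnClass.PHYSICOCHEMICAL.value]
    )
    out = annotated.loc[keep, ["position", "count", "class"]].copy()
    out.insert(0, "paralog", paralog)
    return out.reset_index(drop=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_paralog(p: ParalogConfig, cfg: RunConfig, out_dir: Path) -> dict:
    """Run the full analysis for one paralog; returns its report block."""
    stage = f"[{p.name}]"
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("%s reading catalog %s", stage, p.catalog_path)
    catalog = read_catalog(p.catalog_path, fmt=p.catalog_format)
    n_raw = len(catalog)
    filtered = filter_catalog(catalog, p.window, classes={MutationClass.MISSENSE})
    deduped = dedupe_patients(filtered, key=cfg.dedupe_key)
    logger.info(
        "%s catalog: %d raw -> %d in-window missense -> %d after de-duplication",
        stage, n_raw, len(filtered), len(deduped),
    )
    write_catalog(deduped, out_dir / "filtered_catalog.tsv")

    counts = per_residue_counts(deduped, p.window)
    ks = (
        ks_uniformity_test(deduped.positions(), p.window)
        if len(deduped)
        else None
    )

    logger.info("%s reading alignment %s", stage, p.alignment_path)
    aln = read_alignment(p.alignment_path, reference_id=p.reference_id)
    profile = classify_columns(aln, threshold=cfg.threshold, groups=cfg.similarity_groups)
    rmap = map_columns_to_reference(aln, ref_start=p.ref_start)
    logger.info(
        "%s conservation: %d/%d identical columns (%.1f%%)",
        stage, profile.n_identical(), profile.n_cols, profile.pct_identical(),
    )
    _write_tsv(profile.to_frame(rmap), out_dir / "conservation.tsv")
    _write_tsv(consensus_logo(profile), out_dir / "logo.tsv")

    annotated = annotate_mutations(counts, rmap, profile)
    if annotated.unmapped:
        logger.warning(
            "%s %d mutated position(s) have no alignment column: %s",
            stage, len(annotated.unmapped), annotated.unmapped,
        )
        _write_tsv(
            pd.DataFrame({"position": annotated.unmapped}),
            out_dir / "unmapped_positions.tsv",
        )
    cons_positions = conserved_positions(
        profile, rmap, include_physicochemical=cfg.pool_physicochemical
    )
    conserved_flags = {pos: True for pos in cons_positions}
    _write_tsv(counts_to_frame(counts, conserved_flags), out_dir / "residue_counts.tsv")
    _write_tsv(export_lollipop(annotated.table, p.name), out_dir / "lollipop.tsv")

    n_in_conserved = annotated.n_in_conserved
    if cfg.pool_physicochemical:
        t = annotated.table
        n_in_conserved = int(
            t.loc[
                t["class"].isin(
                    [ColumnClass.IDENTICAL.value, ColumnClass.PHYSICOCHEMICAL.value]
                ),
                "count",
            ].sum()
        )
    enrichment = None
    if len(deduped) and 0 < len(cons_positions) < p.window.length():
        enrichment = chi_square_test(
            EnrichmentInput(
                n_mutations=len(deduped),
                n_in_conserved=n_in_conserved,
                n_conserved=len(cons_positions),
                domain_length=p.window.length(),
            )
        )
        logger.info(
            "%s enrichment: observed %d vs expected %.3f on conserved residues "
            "(chi2=%.3f, p=%.4g)",
            stage, n_in_conserved, enrichment.expected_conserved,
            enrichment.chi_square, enrichment.p_value,
        )
        obs_exp = pd.DataFrame(
            [
                {
                    "paralog": p.name,
                    "class": "conserved",
                    "observed": n_in_conserved,
                    "expected": round(enrichment.expected_conserved, 4),
                },
                {
                    "paralog": p.name,
                    "class": "nonconserved",
                    "observed": len(deduped) - n_in_conserved,
                    "expected": round(enrichment.expected_nonconserved, 4),
                },
            ]
        )
        _write_tsv(obs_exp, out_dir / "observed_vs_expected.tsv")

    block = {
        "paralog": p.name,
        "window": {"start": p.window.start, "end": p.window.end, "length": p.window.length()},
        "counts": {
            "raw": n_raw,
            "in_window_missense": len(filtered),
            "after_dedupe": len(deduped),
        },
        "ks": (
            {"statistic": ks.statistic, "p_value": ks.p_value, "n": ks.n}
            if ks
            else None
        ),
        "conservation": {
            "n_columns": profile.n_cols,
            "n_identical_columns": profile.n_identical(),
            "pct_identical_columns": round(profile.pct_identical(), 1),
            "n_conserved_mapped_residues": len(
                conserved_positions(profile, rmap, include_physicochemical=False)
            ),
            "threshold": cfg.threshold,
            "similarity_groups": list(cfg.similarity_groups),
        },
        "enrichment": enrichment.as_dict() if enrichment else None,
        "unmapped_positions": annotated.unmapped,
    }
    (out_dir / "enrichment.json").write_text(
        json.dumps({"enrichment": block["enrichment"], "ks": block["ks"]}, indent=2, sort_keys=True)
        + "\n"
    )

    if p.wt_structure:
        logger.info("%s structural analysis (cutoff %.1f Å)", stage, cfg.cutoff)
        wt = read_structure(p.wt_structure)
        residues = p.network_residues or [k[1] for k in wt.residues()]
        wt_net = interaction_network(wt, residues, cutoff=cfg.cutoff)
        _write_tsv(interactions_to_frame(wt_net), out_dir / "interactions_wt.tsv")
        block["structure"] = {
            "wt_interactions": len(wt_net),
            "diffs": {},
        }
        for mut_name, mut_path in sorted(p.mut_structures.items()):
            mut = read_structure(mut_path)
            mut_net = interaction_network(mut, residues, cutoff=cfg.cutoff)
            diff = diff_networks(wt_net, mut_net)
            _write_tsv(diff.to_frame(), out_dir / f"diff_{mut_name}.tsv")
            block["structure"]["diffs"][mut_name] = {
                "lost": len(diff.lost),
                "gained": len(diff.gained),
                "retained": len(diff.retained),
            }
            logger.info(
                "%s %s: lost=%d gained=%d retained=%d",
                stage, mut_name, len(diff.lost), len(diff.gained), len(diff.retained),
            )
    return block


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline for every configured paralog.

    Writes per-paralog reports under ``config.out_dir`` and a run
    manifest capturing the package version, every effective threshold
    and a hash of the configuration. Any stage failure aborts with the
    paralog and stage named.
    """
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    bundle: dict = {"version": __version__, "paralogs": []}
    for p in config.paralogs:
        try:
            bundle["paralogs"].append(run_paralog(p, config, out_root / p.name))
        except Exception as exc:
            raise RuntimeError(f"stage failure in paralog {p.name!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "settings": _config_dict(config),
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out_root / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    return bundle


def _config_dict(config: RunConfig) -> dict:
    return {
        "threshold": config.threshold,
        "similarity_groups": list(config.similarity_groups),
        "cutoff": config.cutoff,
        "alpha": config.alpha,
        "seed": config.seed,
        "dedupe_key": config.dedupe_key,
        "pool_physicochemical": config.pool_physicochemical,
        "paralogs": [
            {
                "name": p.name,
                "window": [p.window.start, p.window.end],
                "catalog": p.catalog_path,
                "alignment": p.alignment_path,
                "ref_start": p.ref_start,
                "catalog_format": p.catalog_format,
                "reference_id": p.reference_id,
                "wt_structure": p.wt_structure,
                "mut_structures": dict(sorted(p.mut_structures.items())),
                "network_residues": list(p.network_residues),
            }
            for p in config.paralogs
        ],
    }
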