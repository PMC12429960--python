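"""End-to-end orchestration of the anchor-gene screen.

``run_screen`` executes, per dataset: CPM -> log2(CPM+4) -> anchor drop
detection -> NB-Wald differential expression across the detected drop
transition -> timepoint means -> per-gene anchor correlation; then the
cross-dataset consensus filter and gene-set annotation, with every
intermediate table, threshold and seed written to the output directory.

The DE transition is detected per dataset (each dataset has its own drop
point); ``fixed_transition`` overrides detection everywhere. All thresholds
live in :class:`RunConfig`; CLI flags override config-file values.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import bulk_screen, de_test, geneset_annotate, io_formats
from .io_formats import AnchorscreenError

logger = logging.getLogger("anchorscreen")


@dataclass
class DatasetInput:
    counts: str
    samplesheet: str
    label: str


@dataclass
class RunConfig:
    """Full parameterization of one screen run."""

    anchor: str
    datasets: list[DatasetInput]
    out_dir: str
    r_min: float = 0.6
    min_datasets_r: int = 3
    padj_max: float = 0.05
    alpha: float = 0.05
    test: str = "signed_rank"
    drop_direction: str = "decrease"
    de_rule: str = "all_datasets"
    sets_combine: str = "and"
    signaling_gmt: str | None = None
    puberty_gmt: str | None = None
    fixed_transition: tuple[int, int] | None = None
    seed: int = 0
    overwrite: bool = False
    keep_going: bool = False

    def validate(self) -> None:
        if not self.datasets:
            raise AnchorscreenError("need at least one dataset")
        if not (0 < self.alpha < 1 and 0 < self.padj_max <= 1):
            raise AnchorscreenError("alpha and padj_max must lie in (0, 1]")
        if not (0 <= self.r_min <= 1):
            raise AnchorscreenError("r_min must lie in [0, 1]")
        if self.min_datasets_r < 1:
            raise AnchorscreenError("min_datasets_r must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw["datasets"] = [
            d if isinstance(d, DatasetInput) else DatasetInput(**d)
            for d in raw.get("datasets", [])
        ]
        if raw.get("fixed_transition") is not None:
            raw["fixed_transition"] = tuple(raw["fixed_transition"])
        return cls(**raw)


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {type(h) for h in logger.handlers}
    if logging.StreamHandler not in have:
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def screen_dataset(
    cm: io_formats.CountMatrix,
    dataset_id: str,
    config: RunConfig,
) -> dict:
    """Run all per-dataset stages on one loaded count matrix."""
    t0 = time.perf_counter()
    sub = cm.for_dataset(dataset_id) if len(cm.datasets) > 1 else cm
    norm = bulk_screen.log2cpm4(bulk_screen.cpm(sub))
    drop = bulk_screen.detect_drop(
        norm, config.anchor, alpha=config.alpha, test=config.test,
        dataset_id=dataset_id, direction=config.drop_direction,
    )
    profile = bulk_screen.timepoint_means(norm, dataset_id)
    corr = bulk_screen.correlate_with_anchor(profile, config.anchor)
    if config.fixed_transition is not None:
        transition = config.fixed_transition
    elif drop.drop_index is not None:
        transition = (drop.drop_index - 1, drop.drop_index)
    else:
        transition = None
        if not config.keep_going:
            raise AnchorscreenError(
                f"dataset {dataset_id!r}: no significant anchor "
                f"{config.drop_direction} found (alpha={config.alpha}, "
                f"test={config.test}); pass fixed_transition to proceed"
            )
        logger.warning(
            "dataset %s: no anchor drop detected; keeping correlation "
            "evidence only", dataset_id)
    de = (de_test.de_for_transition(sub, dataset_id, transition)
          if transition is not None else None)
    logger.info(
        "dataset %s: drop index %s (transition %s), %d genes, %.2fs",
        dataset_id, drop.drop_index, transition, len(sub.gene_ids),
        time.perf_counter() - t0,
    )
    return {"drop": drop, "transition": transition, "de": de, "corr": corr}


def screen_count_matrices(
    matrices: dict[str, io_formats.CountMatrix],
    anchor: str,
    r_min: float = 0.6,
    min_datasets_r: int = 3,
    padj_max: float = 0.05,
    alpha: float = 0.05,
    test: str = "rank_sum",
    de_rule: str = "all_datasets",
    keep_going: bool = True,
) -> tuple[bulk_screen.ConsensusTable, dict]:
    """In-memory variant of the screen over already-loaded count matrices.

    Returns the consensus table plus per-dataset detail (drop detection,
    transition used, DE and correlation tables). Correlation with the anchor
    does not depend on the drop transition, so a dataset where no drop is
    detectable still contributes correlation evidence when ``keep_going`` is
    set; only its DE table is absent (listed under ``skipped``). Without
    ``keep_going`` such a dataset raises.
    """
    corr: dict[str, bulk_screen.CorrelationTable] = {}
    de: dict[str, pd.DataFrame] = {}
    detail: dict = {"drops": {}, "transitions": {}, "skipped": {}}
    for ds, cm in matrices.items():
        norm = bulk_screen.log2cpm4(bulk_screen.cpm(cm))
        drop = bulk_screen.detect_drop(norm, anchor, alpha=alpha, test=test,
                                       dataset_id=ds)
        detail["drops"][ds] = drop
        profile = bulk_screen.timepoint_means(norm, ds)
        corr[ds] = bulk_screen.correlate_with_anchor(profile, anchor)
        if drop.drop_index is None:
            if not keep_going:
                raise AnchorscreenError(f"dataset {ds!r}: no anchor drop detected")
            detail["skipped"][ds] = "no anchor drop detected; correlation only"
            continue
        transition = (drop.drop_index - 1, drop.drop_index)
        detail["transitions"][ds] = transition
        de[ds] = de_test.de_for_transition(cm, ds, transition)
    if not de:
        raise AnchorscreenError("no dataset yielded a drop; nothing to combine")
    consensus = bulk_screen.consensus_filter(
        corr, de, r_min=r_min, min_datasets_r=min_datasets_r,
        padj_max=padj_max, de_rule=de_rule,
    )
    detail["corr"] = corr
    detail["de"] = de
    return consensus, detail


def run_screen(config: RunConfig) -> dict:
    """Execute the full multi-dataset screen; returns the output manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    t_start = time.perf_counter()

    stage_results: dict[str, dict] = {}
    failures: dict[str, str] = {}
    for ds in config.datasets:
        cm = io_formats.read_counts(ds.counts, ds.samplesheet)
        try:
            stage_results[ds.label] = screen_dataset(cm, ds.label, config)
        except AnchorscreenError as exc:
            if not config.keep_going:
                raise AnchorscreenError(f"dataset {ds.label!r}: {exc}") from exc
            failures[ds.label] = str(exc)
            logger.warning("dataset %s failed, continuing: %s", ds.label, exc)
    if not stage_results:
        raise AnchorscreenError("every dataset failed; nothing to combine")

    corr_tables = {k: v["corr"] for k, v in stage_results.items()}
    de_tables = {k: v["de"] for k, v in stage_results.items()
                 if v["de"] is not None}
    consensus = bulk_screen.consensus_filter(
        corr_tables, de_tables,
        r_min=config.r_min, min_datasets_r=config.min_datasets_r,
        padj_max=config.padj_max, de_rule=config.de_rule,
    )
    n_undefined = int((~consensus.table.filter(regex="^r_").notna()).all(axis=1).sum())
    if n_undefined:
        logger.warning("%d genes have undefined correlation in every dataset",
                       n_undefined)
    logger.info("consensus: %d of %d genes pass (%d genes common to all datasets)",
                int(consensus.table["pass"].sum()), len(consensus.table),
                consensus.n_genes_common)

    tables: dict[str, pd.DataFrame] = {"consensus": consensus.table}
    for label, res in stage_results.items():
        tables[f"correlation_{label}"] = res["corr"].table
        if res["de"] is not None:
            tables[f"de_{label}"] = res["de"]
        tables[f"drop_{label}"] = pd.DataFrame(
            [t.__dict__ for t in res["drop"].transitions]
        )

    if config.signaling_gmt and config.puberty_gmt:
        signaling = io_formats.read_gmt(config.signaling_gmt)[0]
        puberty_sets = io_formats.read_gmt(config.puberty_gmt)
        puberty = puberty_sets[0]
        for extra in puberty_sets[1:]:
            puberty = geneset_annotate.merge_sets(puberty, extra, "puberty_merged")
        annotated = geneset_annotate.annotate(
            consensus, signaling, puberty,
            combine=config.sets_combine, exclude=(config.anchor,),
        )
        tables["candidates"] = annotated
        tables["final_candidates"] = geneset_annotate.final_candidates(annotated)
        logger.info("final candidates: %d", int(annotated["final"].sum()))

    params = asdict(config)
    params["drop_index_by_dataset"] = {
        k: v["drop"].drop_index for k, v in stage_results.items()
    }
    params["transition_by_dataset"] = {
        k: (list(v["transition"]) if v["transition"] is not None else None)
        for k, v in stage_results.items()
    }
    params["failures"] = failures
    params["n_genes_common"] = consensus.n_genes_common
    manifest = io_formats.write_results(
        tables, out_dir, parameters=params, overwrite=config.overwrite
    )
    manifest["failures"] = failures
    manifest["consensus_pass"] = int(consensus.table["pass"].sum())
    logger.info("screen finished in %.1fs", time.perf_counter() - t_start)
    return manifest


def replay(summary_json: str | Path) -> dict:
    """Re-run a screen from the parameters recorded in its summary.json."""
    params = json.loads(Path(summary_json).read_text())["parameters"]
    keep = {f.name for f in RunConfig.__dataclass_fields__.values()}
    raw = {k: v for k, v in params.items() if k in keep}
    raw["datasets"] = [DatasetInput(**d) for d in raw["datasets"]]
    if raw.get("fixed_transition") is not None:
        raw["fixed_transition"] = tuple(raw["fixed_transition"])
    raw["overwrite"] = True
    return run_screen(RunConfig(**raw))
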