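"""End-to-end orchestration: parse → dedupe → filter → analyse → report.

A run is a pure function of (inputs, config): the manifest written into
every output directory records the config, package version and input
checksums, so identical manifests imply identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .detect import DetectorConfig
from .filters import FilterConfig, filter_records, tally_exclusions
from .records import PaperRecord, dedupe, read_records
from .reuse import (build_reuse_records, reuse_fraction_within,
                    reuse_records_to_frame, t10_by_cohort)
from .trends import (annual_word_counts, annual_trends, frequency_spectrum,
                     top_acronyms, trends_excluding_top, trends_to_frame)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    inputs: tuple[str, ...] = ()
    start_year: int = 1950
    caps_threshold: float = 0.60
    fields: tuple[str, ...] = ("title", "abstract")
    stratify: bool = True
    reuse_window: float = 1.0
    top_k_mask: int = 100
    top_n: int = 20
    min_length: int = 2
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(start_year=self.start_year,
                            caps_threshold=self.caps_threshold)

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(min_length=self.min_length)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 records: Sequence[PaperRecord] | None = None) -> dict:
    """Run every analysis stage and write the report bundle.

    ``records`` may be passed directly (e.g. a synthetic corpus);
    otherwise ``config.inputs`` names JSON-lines record files.  Outputs:
    exclusion tally, per-field trend tables (full and top-k-masked),
    top-N ranking, frequency spectrum, re-use tables and a manifest.
    Returns a dict of the output paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = []
        for path in config.inputs:
            records.extend(read_records(path))
    records = list(records)
    logger.info("stage parse: %d records", len(records))

    records, n_dup = dedupe(records)
    logger.info("stage dedupe: %d kept, %d duplicates removed",
                len(records), n_dup)

    fcfg = config.filter_config()
    dcfg = config.detector_config()
    tally = tally_exclusions(records, fcfg, n_duplicates=n_dup)
    tally.to_csv(out / "exclusions.tsv", sep="\t")

    paths = {"exclusions": out / "exclusions.tsv"}
    kept_by_field = {}
    for field in config.fields:
        kept = filter_records(records, field, fcfg)
        kept_by_field[field] = kept
        logger.info("stage filter[%s]: %d records kept", field, len(kept))
        trends = annual_trends(kept, field, stratify=config.stratify,
                               config=dcfg)
        trends_to_frame(trends).to_csv(out / f"trends_{field}.tsv",
                                       sep="\t", index=False)
        paths[f"trends_{field}"] = out / f"trends_{field}.tsv"
        masked = trends_excluding_top(kept, field, config.top_k_mask,
                                      config=dcfg)
        trends_to_frame(masked).to_csv(
            out / f"trends_{field}_masked_top{config.top_k_mask}.tsv",
            sep="\t", index=False)
        paths[f"trends_{field}_masked"] = \
            out / f"trends_{field}_masked_top{config.top_k_mask}.tsv"
        words = pd.DataFrame(annual_word_counts(kept, field),
                             columns=["year", "mean_words"])
        words.to_csv(out / f"words_{field}.tsv", sep="\t", index=False)
        paths[f"words_{field}"] = out / f"words_{field}.tsv"

    union: dict[str, PaperRecord] = {}
    for kept in kept_by_field.values():
        for rec in kept:
            union.setdefault(rec.paper_id, rec)
    analysable = sorted(union.values(), key=lambda r: r.paper_id)

    ranking = top_acronyms(analysable, "both", n=config.top_n, config=dcfg)
    pd.DataFrame(ranking, columns=["surface", "count"]).to_csv(
        out / "top_acronyms.tsv", sep="\t", index=False)
    paths["top_acronyms"] = out / "top_acronyms.tsv"

    spectrum = frequency_spectrum(analysable, config=dcfg)
    with open(out / "spectrum.json", "w") as fh:
        json.dump(dataclasses.asdict(spectrum), fh, indent=2)
    paths["spectrum"] = out / "spectrum.json"

    reuse_records = build_reuse_records(analysable, config=dcfg)
    reuse_records_to_frame(reuse_records).to_csv(
        out / "reuse_records.tsv", sep="\t", index=False)
    paths["reuse_records"] = out / "reuse_records.tsv"
    frac = reuse_fraction_within(reuse_records, config.reuse_window)
    by_len = reuse_fraction_within(reuse_records, config.reuse_window,
                                   by_length=True)
    with open(out / "reuse_summary.json", "w") as fh:
        json.dump({
            "window_years": config.reuse_window,
            "fraction_reused": frac,
            "fraction_reused_by_length": {str(k): v for k, v in by_len.items()},
        }, fh, indent=2)
    paths["reuse_summary"] = out / "reuse_summary.json"
    t10 = t10_by_cohort(reuse_records)
    t10.to_csv(out / "t10_by_cohort.tsv", sep="\t", index=False)
    paths["t10"] = out / "t10_by_cohort.tsv"

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _checksum(Path(p)) for p in config.inputs},
        "n_records": len(records),
        "n_duplicates_removed": n_dup,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest"] = out / "manifest.json"
    return {k: str(v) for k, v in paths.items()}
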