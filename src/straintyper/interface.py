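"""End-to-end orchestration and the cross-method concordance report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import yaml

from .models import SpectralTyping
from .preprocess import PreprocessParams
from .typing_stats import compare_partitions, simpson_diversity

__all__ = ["RunConfig", "run_ftir_pipeline", "run_concordance_report"]

log = logging.getLogger("straintyper")


@dataclass
class RunConfig:
    """Resolved configuration of an end-to-end run."""

    spectra: str = ""
    metadata: str = ""
    group_by: str = "strain"
    outdir: str = "straintyper_out"
    seed: int = 0
    preprocess: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=False)


def run_ftir_pipeline(cfg: RunConfig):
    """Spectra CSV -> preprocessing -> HCA -> automatic cutoff; writes all
    artifacts (CSV, Newick, JSON report) under ``cfg.outdir``."""
    for path in (cfg.spectra, cfg.metadata):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    params = PreprocessParams(**cfg.preprocess)
    log.info("loading spectra from %s", cfg.spectra)
    model = SpectralTyping.from_csv(cfg.spectra, cfg.metadata,
                                    group_by=cfg.group_by, params=params)
    results = model.fit()
    outdir = Path(cfg.outdir)
    results.save(outdir)
    report = {
        "n_samples": len(results.distances),
        "group_by": cfg.group_by,
        **results.cutoff.to_dict(),
        "parameters": {
            "sg_window": params.sg_window,
            "sg_polyorder": params.sg_polyorder,
            "cut_hi": params.cut_hi,
            "cut_lo": params.cut_lo,
        },
    }
    with open(outdir / "ftir_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("FTIR typing: %d types at cutoff %.6g",
             results.n_types, results.cutoff.height)
    return results


def run_concordance_report(partitions: dict, out_path=None) -> dict:
    """Cross-method typing report over >= 2 partitions of one sample set.

    ``partitions`` maps method name (e.g. ``FTIR``, ``PFGE``, ``MLST``) to
    a :class:`Partition`.  Returns (and optionally writes) a JSON-ready
    dict with per-method Simpson's D, the pairwise Rand/Wallace table, and
    a plain-language concordance summary.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two typing methods to compare")
    names = list(partitions)
    sample_sets = {frozenset(p.samples) for p in partitions.values()}
    if len(sample_sets) != 1:
        raise ValueError("all partitions must cover the same sample set")
    report: dict = {"methods": {}, "comparisons": [], "summary": []}
    for name, p in partitions.items():
        report["methods"][name] = {
            "n_types": p.n_types,
            "type_sizes": p.sizes(),
            "simpson_diversity": simpson_diversity(p),
        }
    for a, b in combinations(names, 2):
        cmpres = compare_partitions(partitions[a], partitions[b], a, b)
        report["comparisons"].append(cmpres.to_dict())
        if cmpres.rand_index == 1.0:
            verdict = "fully concordant"
        elif cmpres.rand_index >= 0.8:
            verdict = "largely concordant"
        else:
            verdict = "discordant"
        report["summary"].append(
            f"{a} ({partitions[a].n_types} types) vs {b} "
            f"({partitions[b].n_types} types): Rand {cmpres.rand_index:.2f} "
            f"— {verdict}"
        )
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
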