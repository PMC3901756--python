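"""End-to-end orchestration: classify -> rates -> profiles -> saturation
-> priors, with provenance-stamped TSV outputs.

Every output carries a comment header recording the tool version, the
seed, and SHA-256 checksums of the inputs, so a result file can always
be traced back to the exact data that produced it. Files are written to
a ``.partial`` name and renamed on completion, so an interrupted run
never leaves a truncated file masquerading as a finished one.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field

from . import __version__
from .alignment import read_fasta
from .informativeness import VARIANTS, profile
from .partitions import PartitionScheme
from .priors import CalibrationPrior
from .rates import SiteRateTable, estimate_all_rates
from .saturation import saturation_table
from .siteclass import summarize
from .tree import PhyloTree

__all__ = ["RunConfig", "ConfigError", "run"]

log = logging.getLogger("phyloinform")


class ConfigError(ValueError):
    """Raised when a run configuration is invalid before any computation."""


@dataclass
class RunConfig:
    alignment: str
    tree: str
    partitions: str
    out_dir: str
    rates_override: str | None = None
    grid_points: int = 512
    t_max: float | None = None  # default: root age of the tree
    variants: tuple = VARIANTS
    priors: list = field(default_factory=list)  # CalibrationPrior objects
    seed: int = 0
    lam_max: float | None = None

    def validate(self) -> None:
        for label, path in [
            ("alignment", self.alignment),
            ("tree", self.tree),
            ("partitions", self.partitions),
        ]:
            if not os.path.exists(path):
                raise ConfigError(f"{label} path does not exist: {path}")
        if self.rates_override and not os.path.exists(self.rates_override):
            raise ConfigError(
                f"rates override does not exist: {self.rates_override}"
            )
        if self.grid_points < 1:
            raise ConfigError("grid_points must be positive")
        if self.t_max is not None and self.t_max <= 0:
            raise ConfigError("t_max must be positive")
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigError(f"unknown PI variant {v!r}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame, path: str, header_lines) -> None:
    tmp = path + ".partial"
    with open(tmp, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    os.replace(tmp, path)


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns a map stage -> output path."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    provenance = [
        f"phyloinform {__version__}",
        f"seed: {config.seed}",
    ] + [
        f"input {p}: sha256 {_sha256(p)}"
        for p in [config.alignment, config.tree, config.partitions]
        + ([config.rates_override] if config.rates_override else [])
    ]

    log.info("loading inputs")
    matrix = read_fasta(config.alignment)
    tree = PhyloTree.read(config.tree)
    scheme = PartitionScheme.read(config.partitions, matrix.n_sites)
    outputs = {}

    def out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    log.info("stage: site classification")
    classes = summarize(matrix, scheme)
    classes = classes.sort_values("partition")
    _write_tsv(
        classes,
        out("site_classes.tsv"),
        provenance + ["note: n_variable includes parsimony-informative sites"],
    )
    outputs["site_classes"] = out("site_classes.tsv")

    if config.rates_override:
        log.info("stage: rates (loading override table)")
        rates = SiteRateTable.read_tsv(config.rates_override)
    else:
        log.info("stage: rates (per-site ML estimation)")
        rates = estimate_all_rates(matrix, tree, scheme, lam_max=config.lam_max)
    _write_tsv(rates.frame, out("site_rates.tsv"), provenance)
    outputs["site_rates"] = out("site_rates.tsv")

    log.info("stage: informativeness profiles")
    t_max = config.t_max if config.t_max is not None else tree.root_age
    pi = profile(
        rates,
        scheme,
        t_max=t_max,
        grid_points=config.grid_points,
        variants=config.variants,
    )
    tidy = pi.frame.sort_values(["partition", "variant", "t_ma"])
    _write_tsv(tidy, out("pi_profiles.tsv"), provenance)
    outputs["pi_profiles"] = out("pi_profiles.tsv")

    log.info("stage: saturation")
    sat = saturation_table(matrix, tree, scheme)
    pairs = sat.pairs.sort_values(["partition", "taxon_a", "taxon_b"])
    _write_tsv(pairs, out("saturation_pairs.tsv"), provenance)
    _write_tsv(sat.summary, out("saturation_summary.tsv"), provenance)
    outputs["saturation_pairs"] = out("saturation_pairs.tsv")
    outputs["saturation_summary"] = out("saturation_summary.tsv")

    if config.priors:
        log.info("stage: calibration priors")
        import pandas as pd

        rows = []
        for prior in config.priors:
            for q in (0.025, 0.05, 0.5, 0.95, 0.975):
                rows.append(
                    {
                        "kind": prior.kind,
                        "offset_ma": prior.offset,
                        "mean": prior.mean,
                        "sd": prior.sd if prior.sd is not None else "",
                        "quantile": q,
                        "age_ma": prior.quantile(q),
                    }
                )
        _write_tsv(pd.DataFrame(rows), out("priors.tsv"), provenance)
        outputs["priors"] = out("priors.tsv")

    log.info("pipeline finished: %d output file(s)", len(outputs))
    return outputs
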