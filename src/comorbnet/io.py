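"""Cohort readers, artifact writers, run configuration and the pipeline.

The pipeline chains the full analysis: cohort (read or simulated) ->
association screening -> one network per (measure, stratum) -> Louvain
communities -> cross-measure comparison reports, with every artifact
written as plain text (CSV / GraphML / GEXF / JSON).  Defaults follow
the standard analysis settings: minimum joint frequency 15, alpha 0.01,
all seven measures, the three edge strata (all, strongest 50%,
strongest 200), prevalence band cut-points at 1% and 7%, and top-20
central nodes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from . import community as community_mod
from . import network as network_mod
from .association import (
    MEASURE_NAMES,
    AssociationRecord,
    AssociationTable,
    ContingencyTable,
    build_association_table,
)
from .compare import build_comparison_report
from .errors import InvalidConfigError
from .network import ALL_EDGES, Selection, top_fraction, top_k
from .synthetic import CohortMatrix, SyntheticConfig, generate_cohort

logger = logging.getLogger("comorbnet")


def read_cohort(
    path: str | Path,
    format: str = "long",
    restrict_multimorbid: bool = False,
) -> CohortMatrix:
    """Read a cohort from long (person_id,condition) or wide binary CSV.

    Long format: duplicate (person, condition) rows collapse to a single
    positive cell.  Wide format: strictly 0/1 cells with a person_id
    index column.  Conditions are ordered lexicographically; persons by
    their identifier.
    """
    path = Path(path)
    if format == "long":
        frame = pd.read_csv(path, dtype=str)
        if list(frame.columns[:2]) != ["person_id", "condition"]:
            raise InvalidConfigError(
                f"long file must have header person_id,condition; got {list(frame.columns)}"
            )
        if frame.empty:
            raise InvalidConfigError(f"{path} contains no records")
        wide = pd.crosstab(frame["person_id"], frame["condition"]).clip(upper=1)
        wide = wide.sort_index().sort_index(axis=1)
    elif format == "wide":
        wide = pd.read_csv(path, index_col="person_id")
        if wide.empty:
            raise InvalidConfigError(f"{path} contains no records")
        bad = wide[~wide.isin([0, 1]).all(axis=1)]
        if not bad.empty:
            raise InvalidConfigError(
                f"wide file has non-binary cells in rows: {list(bad.index[:5])}"
            )
        wide = wide.sort_index().sort_index(axis=1)
    else:
        raise InvalidConfigError(f"unknown format {format!r}")

    values = wide.to_numpy(dtype=np.uint8)
    if restrict_multimorbid:
        values = values[values.sum(axis=1) >= 2]
    incidence = sparse.csr_matrix(values)
    return CohortMatrix(
        incidence=incidence,
        condition_labels=[str(c) for c in wide.columns],
        prevalence=np.asarray(incidence.mean(axis=0)).ravel(),
    )


def write_association_csv(table: AssociationTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_association_csv(
    path: str | Path, min_support: int = 15, alpha: float = 0.01
) -> AssociationTable:
    frame = pd.read_csv(path)
    records = [
        AssociationRecord(
            condition_x=row.pair_x,
            condition_y=row.pair_y,
            table=ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d)),
            p_value=float(row.p_value),
            test_used=row.test_used,
            **{m: float(getattr(row, m)) for m in MEASURE_NAMES},
        )
        for row in frame.itertuples()
    ]
    return AssociationTable(
        records=records,
        n_candidates=len(records),
        n_excluded=0,
        min_support=min_support,
        alpha=alpha,
    )


def write_partition_csv(partition: community_mod.Partition, path: str | Path) -> None:
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["node", "community_id"]
    ).to_csv(path, index=False)


def write_edge_profile_csv(profile: network_mod.EdgeProfile, path: str | Path) -> None:
    rows = [
        {"metric": f"pct_edges_{cls}", "value": pct}
        for cls, pct in profile.band_pair_percentages.items()
    ]
    for name, summary in (
        ("joint_prevalence", profile.joint_prevalence_summary),
        ("prevalence_difference", profile.prevalence_difference_summary),
    ):
        for stat, value in zip(("median", "q1", "q3"), summary):
            rows.append({"metric": f"{name}_{stat}_pct", "value": value})
    pd.DataFrame(rows).to_csv(path, index=False)


def _default_strata() -> list[Selection]:
    return [ALL_EDGES, top_fraction(0.5), top_k(200)]


@dataclass
class RunConfig:
    """End-to-end pipeline settings; defaults are the standard analysis."""

    input_path: str | None = None
    input_format: str = "long"
    synthetic: SyntheticConfig | None = None
    restrict_multimorbid: bool = True
    min_support: int = 15
    alpha: float = 0.01
    continuity_correction: bool = False
    measures: list[str] = field(default_factory=lambda: list(MEASURE_NAMES))
    strata: list[Selection] = field(default_factory=_default_strata)
    band_thresholds: tuple[float, float] = (0.01, 0.07)
    top_central_k: int = 20
    louvain_seed: int = 0
    louvain_resolution: float = 1.0
    output_dir: str = "comorbnet_output"

    def validate(self) -> None:
        if self.input_path is None and self.synthetic is None:
            raise InvalidConfigError("need either input_path or a synthetic config")
        if self.min_support < 1:
            raise InvalidConfigError("min_support must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        unknown = set(self.measures) - set(MEASURE_NAMES)
        if unknown:
            raise InvalidConfigError(f"unknown measures: {sorted(unknown)}")
        lo, hi = self.band_thresholds
        if not (0 < lo < hi < 1):
            raise InvalidConfigError("band thresholds must satisfy 0 < lo < hi < 1")
        if self.top_central_k < 1:
            raise InvalidConfigError("top_central_k must be >= 1")

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a JSON superset
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            syn["prevalence_targets"] = tuple(syn["prevalence_targets"])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "strata" in raw:
            raw["strata"] = [
                Selection(s["kind"], s.get("param")) for s in raw["strata"]
            ]
        if "band_thresholds" in raw:
            raw["band_thresholds"] = tuple(raw["band_thresholds"])
        return RunConfig(**raw)


def _load_cohort(config: RunConfig) -> CohortMatrix:
    if config.synthetic is not None:
        return generate_cohort(config.synthetic)
    return read_cohort(
        config.input_path,
        format=config.input_format,
        restrict_multimorbid=config.restrict_multimorbid,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all artifacts to the output dir.

    Deterministic: identical config and seeds reproduce identical
    artifacts.  Returns the run metadata (also written to run_log.json).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _load_cohort(config)
    logger.info(
        "cohort: %d individuals, %d conditions",
        cohort.n_individuals, cohort.n_conditions,
    )

    assoc = build_association_table(
        cohort,
        min_support=config.min_support,
        alpha=config.alpha,
        continuity_correction=config.continuity_correction,
    )
    logger.info(
        "Out of %d pairwise co-occurrences with joint frequencies >= %d, "
        "%d were excluded; %d associations remained",
        assoc.n_candidates, config.min_support, assoc.n_excluded, len(assoc),
    )
    write_association_csv(assoc, out / "associations.csv")

    prevalence = cohort.prevalence_map()
    stratum_reports: dict[str, dict] = {}
    for stratum in config.strata:
        networks: dict[str, network_mod.DiseaseNetwork] = {}
        partitions: dict[str, community_mod.Partition] = {}
        for measure in config.measures:
            net = network_mod.build_network(
                assoc, measure, stratum, prevalence, config.band_thresholds
            )
            if net.n_edges == 0:
                logger.warning(
                    "skipping %s/%s: no edges kept", measure, stratum.label()
                )
                continue
            tag = f"{measure}_{stratum.label()}"
            network_mod.write_graphml(net, out / f"network_{tag}.graphml")
            network_mod.write_gexf(net, out / f"network_{tag}.gexf")
            network_mod.write_edgelist_csv(net, out / f"edges_{tag}.csv")
            part = community_mod.detect_communities(
                net, seed=config.louvain_seed, resolution=config.louvain_resolution
            )
            write_partition_csv(part, out / f"communities_{tag}.csv")
            write_edge_profile_csv(
                network_mod.edge_profile(net, config.band_thresholds),
                out / f"edge_profile_{tag}.csv",
            )
            networks[measure] = net
            partitions[measure] = part
        if len(networks) >= 2:
            report = build_comparison_report(
                networks, partitions, k=config.top_central_k
            )
            report.to_json(out / f"comparison_{stratum.label()}.json")
            stratum_reports[stratum.label()] = report.to_dict()

    meta = {
        "n_individuals": cohort.n_individuals,
        "n_conditions": cohort.n_conditions,
        "n_candidates": assoc.n_candidates,
        "n_excluded": assoc.n_excluded,
        "n_retained": len(assoc),
        "min_support": config.min_support,
        "alpha": config.alpha,
        "measures": config.measures,
        "strata": [s.label() for s in config.strata],
        "louvain_seed": config.louvain_seed,
        "synthetic_seed": config.synthetic.seed if config.synthetic else None,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    meta["reports"] = stratum_reports
    return meta
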