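"""Reading and writing the pipeline's file formats.

All tabular interchange is delimited text (comma or tab, auto-detected,
UTF-8, header row required).  Networks are exported as GraphML and GEXF
(Gephi-compatible) plus a plain edge list; reports are JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .community import AbundanceTable
from .simulate import GradientScenario, SimulatedDataset
from .trophic import TrophicAssessment, TrophicSummary, WaterChemistryRecord

CHEM_REQUIRED = ("site_id", "tn", "tp", "chl_a", "secchi")
CHEM_OPTIONAL = ("wt", "do", "cod", "ph", "nh4", "no3", "po4", "cond", "orp", "flow")


class TableFormatError(ValueError):
    """A delimited input file violates the expected layout."""


def _sniff_sep(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_chemistry(path) -> list[WaterChemistryRecord]:
    """Load per-site water chemistry from delimited text.

    Requires columns site_id, tn, tp, chl_a, secchi; optional covariates are
    carried into ``extras``.  A units row directly under the header (cells
    that are not numeric) is validated and skipped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str).rename(
        columns=lambda c: c.strip().lower()
    )
    missing = [c for c in CHEM_REQUIRED if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    # optional units row: first data row with non-numeric tn
    if len(df) and not _is_number(df.iloc[0]["tn"]):
        units = df.iloc[0]
        expected = {"tn": "mg/l", "tp": "mg/l", "chl_a": "ug/l", "secchi": "m"}
        for col, want in expected.items():
            got = str(units[col]).strip().lower().replace("μ", "u")
            if got and got != want:
                raise TableFormatError(
                    f"{path}: column {col} declares units {units[col]!r}, expected {want}"
                )
        df = df.iloc[1:]
    records = []
    seen: set[str] = set()
    for pos, row in df.iterrows():
        line = pos + 2  # header line is 1
        site = str(row["site_id"]).strip()
        if not site or site.lower() == "nan":
            raise TableFormatError(f"{path}: line {line}: empty site_id")
        if site in seen:
            raise TableFormatError(f"{path}: line {line}: duplicate site_id {site!r}")
        seen.add(site)
        vals = {}
        for col in ("tn", "tp", "chl_a", "secchi"):
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}: line {line}: field {col} = {row[col]!r} is not numeric"
                ) from None
        extras = {}
        for col in CHEM_OPTIONAL:
            if col in df.columns and _is_number(row[col]):
                extras[col] = float(row[col])
        records.append(
            WaterChemistryRecord(
                site_id=site, tn=vals["tn"], tp=vals["tp"],
                chl_a=vals["chl_a"], secchi=vals["secchi"], extras=extras,
            )
        )
    if not records:
        raise TableFormatError(f"{path}: no data rows")
    return records


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_chemistry(records, path) -> None:
    rows = [
        {"site_id": r.site_id, "tn": r.tn, "tp": r.tp,
         "chl_a": r.chl_a, "secchi": r.secchi, **dict(r.extras)}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_assessments(assessments, records, path) -> None:
    """Per-site chemistry with appended component/composite scores + label."""
    by_site = {r.site_id: r for r in records}
    rows = []
    for a in assessments:
        r = by_site[a.site_id]
        rows.append({
            "site_id": a.site_id, "tn": r.tn, "tp": r.tp,
            "chl_a": r.chl_a, "secchi": r.secchi,
            "tsi_chl": a.tsi_chl, "tsi_tn": a.tsi_tn, "tsi_tp": a.tsi_tp,
            "tsi_sd": a.tsi_sd, "tsi": a.tsi, "label": a.label,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def summary_to_dict(summary: TrophicSummary) -> dict:
    d = dict(summary.__dict__)
    d["counts"] = dict(d["counts"])
    return d


def read_abundance(
    counts_path, taxonomy_path, groups_path=None
) -> AbundanceTable:
    """Load a taxa-by-sample count table plus its taxonomy map.

    Counts: taxa as rows, samples as columns, first column taxon_id.
    Taxonomy: columns taxon_id, kingdom, phylum[, genus].
    Groups (optional): columns sample_id, group with group in {L, M, H}.
    """
    counts_path = Path(counts_path)
    counts = pd.read_csv(counts_path, sep=_sniff_sep(counts_path), index_col=0)
    counts.index = counts.index.astype(str)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{counts_path}: duplicate taxon_id(s) {dup}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise TableFormatError(f"{counts_path}: non-numeric count cells present")
    bad = np.argwhere(arr < 0)
    if bad.size:
        i, j = bad[0]
        raise TableFormatError(
            f"{counts_path}: line {i + 2}: negative count {arr[i, j]} "
            f"(taxon {counts.index[i]}, sample {counts.columns[j]})"
        )
    taxonomy_path = Path(taxonomy_path)
    taxonomy = pd.read_csv(taxonomy_path, sep=_sniff_sep(taxonomy_path), dtype=str)
    taxonomy = taxonomy.rename(columns=lambda c: c.strip().lower())
    for col in ("taxon_id", "kingdom", "phylum"):
        if col not in taxonomy.columns:
            raise TableFormatError(f"{taxonomy_path}: missing column {col}")
    taxonomy = taxonomy.set_index("taxon_id")
    if taxonomy.index.has_duplicates:
        dup = taxonomy.index[taxonomy.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{taxonomy_path}: duplicate taxon_id(s) {dup}")
    group = None
    if groups_path is not None:
        groups_path = Path(groups_path)
        gdf = pd.read_csv(groups_path, sep=_sniff_sep(groups_path), dtype=str)
        gdf = gdf.rename(columns=lambda c: c.strip().lower())
        if "sample_id" not in gdf.columns or "group" not in gdf.columns:
            raise TableFormatError(f"{groups_path}: need columns sample_id, group")
        bad_g = set(gdf["group"]) - {"L", "M", "H"}
        if bad_g:
            raise TableFormatError(f"{groups_path}: unknown group label(s) {sorted(bad_g)}")
        group = gdf.set_index("sample_id")["group"]
    return AbundanceTable(counts=counts, taxonomy=taxonomy, group=group)


def write_abundance(table: AbundanceTable, counts_path, taxonomy_path=None,
                    groups_path=None) -> None:
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(counts_path)
    if taxonomy_path is not None:
        tx = table.taxonomy.copy()
        tx.index.name = "taxon_id"
        tx.to_csv(taxonomy_path)
    if groups_path is not None and table.group is not None:
        g = table.group.rename("group")
        g.index.name = "sample_id"
        g.to_csv(groups_path)


def write_distance_matrix(d: pd.DataFrame, path) -> None:
    d.to_csv(path)


def read_distance_matrix(path) -> pd.DataFrame:
    path = Path(path)
    d = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if list(d.index) != list(d.columns):
        raise TableFormatError(f"{path}: row and column labels differ")
    return d


def export_network(network, basepath) -> dict:
    """Write GraphML, GEXF and an edge-list CSV; returns the paths."""
    basepath = Path(basepath)
    g = network.graph
    paths = {
        "graphml": basepath.with_suffix(".graphml"),
        "gexf": basepath.with_suffix(".gexf"),
        "edges": basepath.with_suffix(".edges.csv"),
    }
    nx.write_graphml(g, paths["graphml"])
    nx.write_gexf(g, paths["gexf"])
    network.edges_table().to_csv(paths["edges"], index=False)
    return {k: str(v) for k, v in paths.items()}


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_scenario(path) -> GradientScenario:
    """Load a GradientScenario from YAML or JSON."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            d = json.load(fh)
        else:
            d = yaml.safe_load(fh)
    return GradientScenario.from_dict(d or {})


def write_scenario(scenario: GradientScenario, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(scenario.to_dict(), fh, indent=2)
        else:
            yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write a simulated dataset plus its truth sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chemistry": outdir / "chemistry.csv",
        "phyto_counts": outdir / "phyto_counts.csv",
        "bact_counts": outdir / "bact_counts.csv",
        "taxonomy": outdir / "taxonomy.csv",
        "groups": outdir / "groups.csv",
        "truth": outdir / "truth.json",
    }
    write_chemistry(ds.chemistry, paths["chemistry"])
    write_abundance(ds.phyto, paths["phyto_counts"])
    write_abundance(ds.bact, paths["bact_counts"], paths["taxonomy"], paths["groups"])
    truth = ds.truth
    write_json(
        {
            "sites": truth.sites.reset_index().to_dict(orient="records"),
            "block_membership": truth.block_membership,
            "dominance": truth.dominance,
            "latent_correlation": {
                g: m.to_dict(orient="split") for g, m in truth.latent_correlation.items()
            },
            "scenario": truth.scenario.to_dict(),
        },
        paths["truth"],
    )
    return {k: str(v) for k, v in paths.items()}
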