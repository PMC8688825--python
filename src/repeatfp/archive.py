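"""RepeatExplorer-style comparative archive dialect: write, parse, filter.

A comparative archive is a directory tree
``seqclust/clustering/clusters/dir_CL<n>/index.html`` with one page per
cluster holding two species x species HTML tables — the observed-edges counts
and the observed/expected ratios (``NA`` marking undefined cells) — plus a
``COMPARATIVE_ANALYSIS_COUNTS.csv`` with per-cluster, per-species read
counts.  Real archives contain much more; this dialect keeps exactly what the
fingerprint method consumes, and the parser finds the tables by caption text
first and positional order second (mirroring the html2txt + copy workflow
used on real archives).

Filtering applies the method's cluster-exclusion rules: species-specific
clusters (no between-species matrix), clusters annotated as contamination,
and clusters whose obs/exp matrix contains NA cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree, html as lxml_html

from .matrices import PairMatrix

__all__ = [
    "ClusterRecord",
    "write_archive",
    "parse_archive",
    "filter_records",
    "impute_na",
]

logger = logging.getLogger(__name__)

FLAGS = ("species_specific", "contamination", "has_na")
_EDGES_CAPTION = "Observed edges between species"
_OBS_CAPTION = "Observed/expected edges between species"
_CONTAMINATION_TOKEN = "contamination"


@dataclass
class ClusterRecord:
    """Everything the method keeps about one repeat cluster."""

    cluster_id: int
    edges: PairMatrix
    obs_exp: PairMatrix | None
    read_counts: dict[str, int] = field(default_factory=dict)
    annotations: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.flags = set(self.flags)
        if self.obs_exp is None:
            self.flags.add("species_specific")
            self.flags.discard("has_na")
        elif self.obs_exp.has_na:
            self.flags.add("has_na")
        else:
            self.flags.discard("has_na")
        if any(_CONTAMINATION_TOKEN in k.lower() for k in self.annotations):
            self.flags.add("contamination")
        for label, prop in self.annotations.items():
            if not 0.0 <= prop <= 1.0:
                raise ValueError(f"annotation proportion out of [0,1] for {label!r}")

    @property
    def size(self) -> int:
        return int(sum(self.read_counts.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClusterRecord):
            return NotImplemented
        return (
            self.cluster_id == other.cluster_id
            and self.edges == other.edges
            and (self.obs_exp is None) == (other.obs_exp is None)
            and (self.obs_exp is None or self.obs_exp == other.obs_exp)
            and self.read_counts == other.read_counts
            and self.annotations == other.annotations
            and self.flags == other.flags
        )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    if np.isnan(v):
        return "NA"
    if float(v).is_integer():
        return str(int(v))
    return format(float(v), ".17g")


def _matrix_table(matrix: PairMatrix, caption: str) -> etree._Element:
    table = etree.Element("table")
    etree.SubElement(table, "caption").text = caption
    head = etree.SubElement(table, "tr")
    etree.SubElement(head, "th").text = ""
    for sp in matrix.species:
        etree.SubElement(head, "th").text = str(sp)
    for sp, row in matrix.data.iterrows():
        tr = etree.SubElement(table, "tr")
        etree.SubElement(tr, "th").text = str(sp)
        for v in row:
            etree.SubElement(tr, "td").text = _fmt(v)
    return table


def write_archive(records: list[ClusterRecord], out_dir) -> Path:
    """Emit the archive directory; returns its path."""
    ids = [r.cluster_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("cluster ids must be unique")
    out_dir = Path(out_dir)
    clusters_dir = out_dir / "seqclust" / "clustering" / "clusters"
    clusters_dir.mkdir(parents=True, exist_ok=True)

    species: list[str] = []
    for rec in records:
        for sp in rec.read_counts:
            if sp not in species:
                species.append(sp)

    for rec in records:
        page = etree.Element("html")
        body = etree.SubElement(page, "body")
        etree.SubElement(body, "h1").text = f"CL{rec.cluster_id}"
        body.append(_matrix_table(rec.edges, _EDGES_CAPTION))
        if rec.obs_exp is not None:
            body.append(_matrix_table(rec.obs_exp, _OBS_CAPTION))
        if rec.annotations:
            ann = etree.SubElement(body, "table")
            ann.set("class", "annotations")
            etree.SubElement(ann, "caption").text = "Annotations"
            for label in sorted(rec.annotations):
                tr = etree.SubElement(ann, "tr")
                etree.SubElement(tr, "th").text = label
                etree.SubElement(tr, "td").text = format(rec.annotations[label], ".17g")
        d = clusters_dir / f"dir_CL{rec.cluster_id}"
        d.mkdir(parents=True, exist_ok=True)
        (d / "index.html").write_bytes(
            etree.tostring(page, pretty_print=True, method="html")
        )

    counts = pd.DataFrame(
        [[rec.cluster_id] + [rec.read_counts.get(sp, 0) for sp in species]
         for rec in records],
        columns=["cluster"] + species,
    )
    counts.to_csv(out_dir / "COMPARATIVE_ANALYSIS_COUNTS.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_table(table: etree._Element) -> pd.DataFrame:
    rows = table.findall("tr")
    header = [c.text or "" for c in rows[0]]
    cols = header[1:]
    index, values = [], []
    for tr in rows[1:]:
        cells = list(tr)
        index.append(cells[0].text or "")
        vals = []
        for td in cells[1:]:
            text = (td.text or "").strip()
            vals.append(np.nan if text == "NA" else float(text))
        values.append(vals)
    df = pd.DataFrame(values, index=index, columns=cols)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError("non-square table or asymmetric headers")
    return df


def _classify_tables(body) -> tuple[object | None, object | None, object | None]:
    """Locate edges / obs-exp / annotation tables by caption, then by position."""
    edges_t = obs_t = ann_t = None
    positional = []
    for table in body.iter("table"):
        cap = table.find("caption")
        cap_text = (cap.text or "").lower() if cap is not None else ""
        if table.get("class") == "annotations" or cap_text.startswith("annotation"):
            ann_t = table
        elif "observed/expected" in cap_text:
            obs_t = table
        elif "observed" in cap_text:
            edges_t = table
        else:
            positional.append(table)
    if edges_t is None and positional:
        edges_t = positional.pop(0)
    if obs_t is None and positional:
        obs_t = positional.pop(0)
    return edges_t, obs_t, ann_t


def parse_archive(archive_dir) -> list[ClusterRecord]:
    """Parse an archive directory back into :class:`ClusterRecord` objects.

    Malformed cluster pages are skipped with a logged warning; a missing or
    unparsable obs/exp table marks the cluster species-specific (the "0-kb
    obs file" case of real archives).
    """
    archive_dir = Path(archive_dir)
    clusters_dir = archive_dir / "seqclust" / "clustering" / "clusters"
    if not clusters_dir.is_dir():
        raise FileNotFoundError(f"not an archive directory: {archive_dir}")

    counts_path = archive_dir / "COMPARATIVE_ANALYSIS_COUNTS.csv"
    counts: dict[int, dict[str, int]] = {}
    if counts_path.exists():
        cdf = pd.read_csv(counts_path)
        for row in cdf.itertuples(index=False):
            d = row._asdict()
            cid = int(d.pop("cluster"))
            counts[cid] = {sp: int(v) for sp, v in d.items()}

    records = []
    dirs = sorted(
        clusters_dir.glob("dir_CL*"),
        key=lambda p: int(p.name.removeprefix("dir_CL")),
    )
    for d in dirs:
        cid = int(d.name.removeprefix("dir_CL"))
        try:
            page = lxml_html.parse(str(d / "index.html"))
            body = page.getroot()
            edges_t, obs_t, ann_t = _classify_tables(body)
            if edges_t is None:
                raise ValueError("no edges table found")
            edges = PairMatrix(_parse_table(edges_t), "edges")
            obs_exp = None
            if obs_t is not None:
                obs_exp = PairMatrix(_parse_table(obs_t), "obs_exp")
            annotations = {}
            if ann_t is not None:
                for tr in ann_t.findall("tr"):
                    cells = list(tr)
                    if len(cells) == 2:
                        annotations[cells[0].text or ""] = float(cells[1].text)
            records.append(
                ClusterRecord(
                    cluster_id=cid,
                    edges=edges,
                    obs_exp=obs_exp,
                    read_counts=counts.get(cid, {}),
                    annotations=annotations,
                )
            )
        except Exception as exc:  # malformed page: collect and continue
            logger.warning("skipping cluster %s: %s", d.name, exc)
    return records


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_records(
    records: list[ClusterRecord],
    drop_na: bool = True,
    drop_contamination: bool = True,
    drop_species_specific: bool = True,
) -> tuple[list[ClusterRecord], dict[str, int]]:
    """Apply the cluster-exclusion rules; return kept records and a report.

    A cluster is counted under the *first* matching removal reason, in the
    order species_specific -> contamination -> has_na, so the report always
    satisfies kept + sum(removed) == total.
    """
    report = {"species_specific": 0, "contamination": 0, "has_na": 0}
    active = {
        "species_specific": drop_species_specific,
        "contamination": drop_contamination,
        "has_na": drop_na,
    }
    kept = []
    for rec in records:
        reason = next(
            (f for f in FLAGS if active[f] and f in rec.flags),
            None,
        )
        if reason is None:
            kept.append(rec)
        else:
            report[reason] += 1
    return kept, report


def impute_na(
    record: ClusterRecord, strategy: str = "one_edge_equivalent"
) -> ClusterRecord:
    """Replace NA cells of the obs/exp matrix with an artificial value.

    ``one_edge_equivalent``: an NA cell gets 1/(1+E), the ratio scale of a
    single observed edge against the cluster's total; ``row_mean``: the mean
    of the row's non-NA cells (symmetrized).  An optional alternative to
    dropping NA clusters; off by default, as in the method's main analyses.
    """
    if record.obs_exp is None:
        raise ValueError("species-specific cluster has no obs/exp matrix to impute")
    vals = record.obs_exp.to_numpy().copy()
    na = np.isnan(vals)
    if not na.any():
        return record
    if strategy == "one_edge_equivalent":
        E = np.triu(record.edges.to_numpy()).sum()
        vals[na] = 1.0 / (1.0 + E)
    elif strategy == "row_mean":
        means = np.nanmean(np.where(na, np.nan, vals), axis=1)
        means = np.nan_to_num(means, nan=0.0)
        fill = (means[:, None] + means[None, :]) / 2.0
        vals[na] = fill[na]
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    return ClusterRecord(
        cluster_id=record.cluster_id,
        edges=record.edges,
        obs_exp=PairMatrix(vals, "obs_exp", species=record.obs_exp.species),
        read_counts=dict(record.read_counts),
        annotations=dict(record.annotations),
        flags=record.flags - {"has_na"},
    )
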