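"""Gene -> GO annotation input: GAF and QuickGO readers, aspect/evidence filters.

Annotation sources describe which ontology terms a gene product is annotated
with, under which GO aspect (MF/BP/CC) and with which evidence code.  The
``IEA`` code ("Inferred from Electronic Annotation") marks computational,
non-curated assignments; analyses are typically run both with and without it,
so filtering keeps that switch explicit (``iea_mode`` = ``include`` |
``exclude``).

NOT-qualified annotations assert *absence* of function and are dropped.
"""

from __future__ import annotations

import csv
import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

from .errors import DataError, FormatError
from .obo_graph import NAMESPACE_ASPECTS, OntologyGraph
from .errors import UnknownTermError

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationRecord",
    "GeneAnnotationSet",
    "read_gaf",
    "read_quickgo_tsv",
    "read_labels",
    "filter_annotations",
    "fetch_quickgo",
    "QuickGoError",
    "RetriableQuickGoError",
]

_GAF_COLUMNS = 17
_ASPECT_CODES = {"F": "MF", "P": "BP", "C": "CC"}


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    go_id: str
    evidence_code: str
    aspect: Literal["MF", "BP", "CC"]
    qualifier: str = ""


@dataclass
class GeneAnnotationSet:
    """A gene/protein with its filtered set of canonical GO term IDs."""

    gene_id: str
    terms: set[str]
    aspect: str


def read_gaf(path) -> list[AnnotationRecord]:
    """Read a 17-column GAF 2.x file; '!' lines are comments.

    Rows whose qualifier contains ``NOT`` are dropped (and counted in the
    log).  Column meanings follow the GAF spec: 2 = DB Object ID, 4 =
    Qualifier, 5 = GO ID, 7 = Evidence Code, 9 = Aspect.
    """
    records: list[AnnotationRecord] = []
    n_not = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _GAF_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_GAF_COLUMNS} tab-separated "
                    f"columns, found {len(cols)}"
                )
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            aspect = _ASPECT_CODES.get(cols[8])
            if aspect is None:
                raise FormatError(
                    f"{path}:{lineno}: unknown aspect code {cols[8]!r}"
                )
            records.append(
                AnnotationRecord(
                    gene_id=cols[1],
                    go_id=cols[4],
                    evidence_code=cols[6],
                    aspect=aspect,
                    qualifier=qualifier,
                )
            )
    if n_not:
        log.info("read_gaf: dropped %d NOT-qualified rows", n_not)
    return records


def read_quickgo_tsv(path) -> list[AnnotationRecord]:
    """Read a QuickGO annotation-export TSV.

    Requires columns GENE PRODUCT ID, GO TERM, GO ASPECT, GO EVIDENCE CODE
    (QUALIFIER honored when present).
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        needed = {"GENE PRODUCT ID", "GO TERM", "GO ASPECT", "GO EVIDENCE CODE"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: missing QuickGO columns {sorted(needed)}"
            )
        for row in reader:
            qualifier = row.get("QUALIFIER", "") or ""
            if "NOT" in qualifier.split("|"):
                continue
            aspect = _normalize_aspect(row["GO ASPECT"])
            records.append(
                AnnotationRecord(
                    gene_id=row["GENE PRODUCT ID"],
                    go_id=row["GO TERM"],
                    evidence_code=row["GO EVIDENCE CODE"],
                    aspect=aspect,
                    qualifier=qualifier,
                )
            )
    return records


def _normalize_aspect(value: str) -> str:
    v = value.strip()
    if v in _ASPECT_CODES:
        return _ASPECT_CODES[v]
    if v.upper() in ("MF", "BP", "CC"):
        return v.upper()
    lowered = v.lower().replace(" ", "_")
    if lowered in NAMESPACE_ASPECTS:
        return NAMESPACE_ASPECTS[lowered]
    raise FormatError(f"unrecognized GO aspect {value!r}")


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV of (gene_id, class label); '#' lines are comments."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            labels[cols[0]] = cols[1]
    return labels


def filter_annotations(
    records: Iterable[AnnotationRecord],
    aspect: Literal["MF", "BP", "CC"],
    iea_mode: Literal["include", "exclude"] = "include",
    graph: OntologyGraph | None = None,
) -> list[GeneAnnotationSet]:
    """Filter records to one aspect and evidence regime; group by gene.

    ``exclude`` drops IEA-evidence records.  When a graph is supplied,
    alternate term IDs are resolved to canonical ones, obsolete or unknown
    terms are dropped with a warning, and terms whose namespace contradicts
    the requested aspect are dropped.  Genes left with empty term sets are
    omitted.  Output is sorted by gene ID.
    """
    if iea_mode not in ("include", "exclude"):
        raise DataError(f"iea_mode must be include|exclude, got {iea_mode!r}")
    by_gene: dict[str, set[str]] = {}
    for rec in records:
        if rec.aspect != aspect:
            continue
        if iea_mode == "exclude" and rec.evidence_code == "IEA":
            continue
        term = rec.go_id
        if graph is not None:
            try:
                term = graph.resolve(term)
            except UnknownTermError as exc:
                log.warning("dropping annotation %s -> %s: %s",
                            rec.gene_id, rec.go_id, exc)
                continue
            if NAMESPACE_ASPECTS.get(graph.terms[term].namespace) != aspect:
                log.warning(
                    "dropping annotation %s -> %s: namespace does not match "
                    "aspect %s", rec.gene_id, term, aspect,
                )
                continue
        by_gene.setdefault(rec.gene_id, set()).add(term)
    return [
        GeneAnnotationSet(gene, terms, aspect)
        for gene, terms in sorted(by_gene.items())
        if terms
    ]


# -- QuickGO REST access (optional, network) -----------------------------------


class QuickGoError(DataError):
    """QuickGO API returned an error response."""


class RetriableQuickGoError(QuickGoError):
    """Transient network failure; the request can be retried."""


_QUICKGO_URL = "https://www.ebi.ac.uk/QuickGO/services/annotation/search"


def _default_fetch_page(url: str) -> dict:
    try:
        req = urllib.request.Request(url, headers={"Accept": "application/json"})
        with urllib.request.urlopen(req, timeout=60) as resp:
            if resp.status != 200:
                raise QuickGoError(f"QuickGO HTTP {resp.status} for {url}")
            return json.load(resp)
    except urllib.error.URLError as exc:
        raise RetriableQuickGoError(f"network failure contacting QuickGO: {exc}")


def fetch_quickgo(
    gene_ids: Sequence[str],
    aspect: Literal["MF", "BP", "CC"],
    fetch_page: Callable[[str], dict] | None = None,
    page_size: int = 100,
    pause_s: float = 0.0,
) -> list[AnnotationRecord]:
    """Download annotations from the QuickGO REST API (paginated).

    ``fetch_page`` maps a URL to a parsed JSON page and exists so tests can
    inject canned pages; the default uses :mod:`urllib`.  Returns the same
    record schema as the file readers.
    """
    fetch = fetch_page or _default_fetch_page
    aspect_param = {"MF": "molecular_function", "BP": "biological_process",
                    "CC": "cellular_component"}[aspect]
    records: list[AnnotationRecord] = []
    page = 1
    while True:
        params = urllib.parse.urlencode(
            {
                "geneProductId": ",".join(gene_ids),
                "aspect": aspect_param,
                "limit": page_size,
                "page": page,
            }
        )
        data = fetch(f"{_QUICKGO_URL}?{params}")
        for row in data.get("results", []):
            qualifier = row.get("qualifier", "") or ""
            if "NOT" in qualifier.split("|"):
                continue
            records.append(
                AnnotationRecord(
                    gene_id=row["geneProductId"],
                    go_id=row["goId"],
                    evidence_code=row.get("goEvidence", ""),
                    aspect=aspect,
                    qualifier=qualifier,
                )
            )
        page_info = data.get("pageInfo") or {}
        total = page_info.get("total", page)
        if page >= total:
            break
        page += 1
        if pause_s:
            time.sleep(pause_s)
    return records
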