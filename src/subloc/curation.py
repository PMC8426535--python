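"""Dataset curation: annotation filters, class selection, stratified
train/test splitting, and the alignment-based redundancy filter.

The filters encode the construction rules of a curated localization corpus:
keep proteins whose existence evidence is at protein or transcript level,
drop fragments, drop organelle-encoded proteins, and drop sequences that do
not start with methionine or are shorter than 40 residues. Suborganelle
classes are kept only when they have more than a minimum number of members
(default 50, strict). The test split takes, per class, about 15% of the
samples, preferring records created after a year cutoff (2018) and filling
any shortfall by a seeded random draw. Finally, training sequences too
similar to a test sequence are removed using precomputed pairwise alignment
hits: a training protein goes if some hit to a test protein covers more
than 80% of the shorter sequence and has identity above 40% or E-value at
or below 1e-5. No aligner is invoked here — the filter consumes BLAST
tabular output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignmentHit",
    "SplitPlan",
    "DEFAULT_RULES",
    "filter_records",
    "select_classes",
    "split_test",
    "redundancy_filter",
    "read_blast_tab",
    "read_annotations",
    "write_annotations",
]


@dataclass
class AlignmentHit:
    query: str
    subject: str
    identity: float  # percent, 0-100
    length: int  # alignment length
    evalue: float
    qlen: int
    slen: int

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclass
class SplitPlan:
    assignment: dict  # accession -> "train" | "test"
    test_fraction: dict  # class -> achieved fraction
    provenance: dict  # accession -> "year" | "random" (test records only)
    seed: int


# ---------------------------------------------------------------------------
# record filters
# ---------------------------------------------------------------------------

def _need(rec, attr, rule):
    val = getattr(rec, attr, None)
    if val is None:
        raise ValueError(f"rule {rule!r} needs field {attr!r} on {rec.accession}")
    return val


def _rule_existence(rec):
    return _need(rec, "existence_level", "existence") in ("protein", "transcript")


def _rule_fragment(rec):
    return not _need(rec, "is_fragment", "fragment")


def _rule_organelle_encoded(rec):
    return not _need(rec, "organelle_encoded", "organelle_encoded")


def _rule_met_start(rec):
    return rec.sequence.startswith("M")


def _rule_min_length(rec):
    return len(rec.sequence) >= 40  # "fewer than 40" removed, 40 kept


DEFAULT_RULES = (
    ("existence", _rule_existence),
    ("fragment", _rule_fragment),
    ("organelle_encoded", _rule_organelle_encoded),
    ("met_start", _rule_met_start),
    ("min_length", _rule_min_length),
)


def filter_records(records, rules=DEFAULT_RULES):
    """Keep records passing every enabled rule; tally rejections per rule.

    The tally attributes each rejected record to the first failing rule in
    application order; the kept set is order-independent (the rules are a
    pure conjunction).
    """
    kept = []
    tally = {name: 0 for name, _ in rules}
    for rec in records:
        for name, pred in rules:
            if not pred(rec):
                tally[name] += 1
                break
        else:
            kept.append(rec)
    return kept, tally


# ---------------------------------------------------------------------------
# class selection
# ---------------------------------------------------------------------------

def select_classes(records, h, min_count: int = 50):
    """Retain suborganelle classes with more than `min_count` members.

    Labels of dropped classes are removed from (copies of) the records;
    the corresponding organelle labels are kept, so a protein whose only
    suborganelle label is dropped becomes organelle-only.
    """
    from copy import copy

    counts: dict = {}
    for rec in records:
        for sub in rec.suborganelle_labels:
            counts[sub] = counts.get(sub, 0) + 1
    retained = {s for s, n in counts.items() if n > min_count}
    out = []
    for rec in records:
        dropped = rec.suborganelle_labels - retained
        if dropped:
            rec = copy(rec)
            extra_orgs = {h.organelle_of(s) for s in dropped if s in h.name_to_cell}
            rec.suborganelle_labels = rec.suborganelle_labels & retained
            rec.organelle_labels = set(rec.organelle_labels) | extra_orgs
        out.append(rec)
    return sorted(retained), out


# ---------------------------------------------------------------------------
# test split
# ---------------------------------------------------------------------------

def split_test(records, fraction: float = 0.15, year_cutoff: int = 2018,
               seed: int = 0) -> SplitPlan:
    """Per-class test selection: post-cutoff records first, random fill after.

    The per-class quota is ceil(fraction * class size), so every class with
    at least two members contributes to the test set. A record annotated to
    several classes goes to test globally as soon as one class selects it.
    Classes are the suborganelle labels for lv2-annotated records and the
    organelle labels for organelle-only records.
    """
    rng = np.random.default_rng(seed)
    classes: dict = {}
    for i, rec in enumerate(records):
        labels = rec.suborganelle_labels or rec.organelle_labels
        for lab in labels:
            classes.setdefault(lab, []).append(i)

    assignment = {rec.accession: "train" for rec in records}
    provenance: dict = {}
    for lab in sorted(classes):
        members = classes[lab]
        if len(members) < 2:
            warnings.warn(f"class {lab!r} has fewer than 2 members; kept in train")
            continue
        quota = math.ceil(fraction * len(members))
        post = [i for i in members
                if (records[i].created_year or 0) > year_cutoff]
        if len(post) >= quota:
            chosen = list(rng.choice(post, size=quota, replace=False))
            source = {i: "year" for i in chosen}
        else:
            rest = [i for i in members if i not in post]
            fill = list(rng.choice(rest, size=quota - len(post), replace=False))
            chosen = post + fill
            source = {i: ("year" if i in post else "random") for i in chosen}
        for i in chosen:
            acc = records[i].accession
            assignment[acc] = "test"
            provenance.setdefault(acc, source[i])

    achieved = {}
    for lab, members in classes.items():
        n_test = sum(
            1 for i in members if assignment[records[i].accession] == "test"
        )
        achieved[lab] = n_test / len(members)
    return SplitPlan(assignment=assignment, test_fraction=achieved,
                     provenance=provenance, seed=seed)


# ---------------------------------------------------------------------------
# redundancy filter
# ---------------------------------------------------------------------------

def redundancy_filter(train_ids, test_ids, hits, identity_cut: float = 40.0,
                      evalue_cut: float = 1e-5, coverage_cut: float = 0.8,
                      strict_identity: bool = True):
    """Drop training sequences with a strong alignment to any test sequence.

    A train record is removed iff some hit satisfies
    coverage = alignment length / min(qlen, slen) > coverage_cut AND
    (identity > identity_cut OR E-value <= evalue_cut).
    With strict_identity=False the identity comparison becomes >=.
    Returns (retained train ids in input order, removal log).
    """
    train_set, test_set = set(train_ids), set(test_ids)
    removed: dict = {}
    for hit in hits:
        if hit.query not in train_set:
            raise ValueError(f"hit query {hit.query!r} is not a train id")
        if hit.subject not in test_set:
            raise ValueError(f"hit subject {hit.subject!r} is not a test id")
        coverage = hit.length / min(hit.qlen, hit.slen)
        ident_hit = (
            hit.identity > identity_cut
            if strict_identity
            else hit.identity >= identity_cut
        )
        if coverage > coverage_cut and (ident_hit or hit.evalue <= evalue_cut):
            removed.setdefault(hit.query, hit)
    retained = [t for t in train_ids if t not in removed]
    log = [
        {
            "query": q,
            "subject": h.subject,
            "identity": h.identity,
            "evalue": h.evalue,
            "coverage": h.length / min(h.qlen, h.slen),
        }
        for q, h in removed.items()
    ]
    return retained, log


# ---------------------------------------------------------------------------
# I/O: BLAST tabular and annotation tables
# ---------------------------------------------------------------------------

#: outfmt 6 default columns extended with qlen/slen (as produced by
#: -outfmt "6 std qlen slen")
BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore qlen slen"
).split()


def read_blast_tab(path, columns=None):
    """Read BLAST tabular output into AlignmentHits.

    `columns` configures the column order; qseqid, sseqid, pident, length,
    evalue, qlen and slen are required somewhere in it.
    """
    cols = list(columns or BLAST_COLUMNS)
    idx = {}
    for need in ("qseqid", "sseqid", "pident", "length", "evalue", "qlen", "slen"):
        if need not in cols:
            raise ValueError(f"column {need!r} missing from BLAST column spec")
        idx[need] = cols.index(need)
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(cols):
                raise ValueError(f"{path}:{lineno}: expected {len(cols)} columns")
            hits.append(
                AlignmentHit(
                    query=parts[idx["qseqid"]],
                    subject=parts[idx["sseqid"]],
                    identity=float(parts[idx["pident"]]),
                    length=int(parts[idx["length"]]),
                    evalue=float(parts[idx["evalue"]]),
                    qlen=int(parts[idx["qlen"]]),
                    slen=int(parts[idx["slen"]]),
                )
            )
    return hits


_ANN_COLS = [
    "accession", "organelles", "suborganelles", "evidence_experimental",
    "created_year", "cleavage_site", "existence_level", "is_fragment",
    "organelle_encoded",
]


def write_annotations(records, path) -> None:
    """Annotation TSV: one row per record, semicolon-separated label sets."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_COLS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.accession,
                        ";".join(sorted(rec.organelle_labels)),
                        ";".join(sorted(rec.suborganelle_labels)),
                        "1" if rec.evidence_experimental else "0",
                        str(rec.created_year or ""),
                        str(rec.cleavage_site or ""),
                        rec.existence_level or "",
                        "" if rec.is_fragment is None else str(int(rec.is_fragment)),
                        ""
                        if rec.organelle_encoded is None
                        else str(int(rec.organelle_encoded)),
                    ]
                )
                + "\n"
            )


def read_annotations(path, sequences: dict):
    """Read the annotation TSV back; `sequences` maps accession -> sequence."""
    from .encoding import ProteinRecord

    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: header.index(name) for name in header}
        for line in fh:
            parts = line.rstrip("\n").split("\t")

            def get(name, default=""):
                return parts[col[name]] if name in col else default

            acc = get("accession")
            if acc not in sequences:
                raise ValueError(f"no sequence for accession {acc!r}")
            records.append(
                ProteinRecord(
                    accession=acc,
                    sequence=sequences[acc],
                    organelle_labels=set(filter(None, get("organelles").split(";"))),
                    suborganelle_labels=set(
                        filter(None, get("suborganelles").split(";"))
                    ),
                    evidence_experimental=get("evidence_experimental") == "1",
                    created_year=int(get("created_year"))
                    if get("created_year")
                    else None,
                    cleavage_site=int(get("cleavage_site"))
                    if get("cleavage_site")
                    else None,
                    existence_level=get("existence_level") or None,
                    is_fragment=bool(int(get("is_fragment")))
                    if get("is_fragment")
                    else None,
                    organelle_encoded=bool(int(get("organelle_encoded")))
                    if get("organelle_encoded")
                    else None,
                )
            )
    return records
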