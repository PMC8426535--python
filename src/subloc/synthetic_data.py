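"""Synthetic planted-motif proteomes for desk-scale testing.

The generator emulates the statistical structure that sorting-signal
analysis assumes: classes of proteins carrying an N-terminal
signal-peptide-like stretch (a methionine, one positively charged residue,
then a run of hydrophobic residues, with the cleavage site recorded at the
motif end), a C-terminal peroxisomal-targeting-style tripeptide (SKL/SRL/SRM
mixture), or an internal nuclear-localization-style run of 4-5 lysines or
arginines, on top of a background of residues drawn i.i.d. from a fixed
letter distribution. Motif coordinates are recorded as ground truth so
attention-interpretation claims can be scored exactly. A companion generator
emits pairwise alignment-hit tables with planted identities/coverages so the
redundancy filter's expected removals are known by construction.

Everything is seeded: the same configuration and seed give byte-identical
FASTA/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import AlignmentHit
from .encoding import AA_ORDER, ProteinRecord
from .hierarchy import LabelHierarchy, load_hierarchy

__all__ = [
    "MotifSpec",
    "ClassSpec",
    "SimConfig",
    "simulate_proteome",
    "simulate_hits",
    "default_sim_config",
    "toy_hierarchy",
    "signal_peptide_motif",
    "pts1_motif",
    "nls_motif",
]

#: background letter frequencies, approximately the SwissProt composition
BACKGROUND_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0973, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


@dataclass
class MotifSpec:
    """A planted motif: placement, per-position letter distributions.

    `columns[i]` is a dict letter -> probability (summing to 1) for motif
    position i+1. For N-terminal motifs the cleavage site is recorded at the
    last motif residue (`cleavage_at_end`).
    """

    placement: str  # "Nterm" | "Cterm" | "internal"
    columns: list
    cleavage_at_end: bool = False

    def __post_init__(self):
        if self.placement not in ("Nterm", "Cterm", "internal"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if len(self.columns) < 3:
            raise ValueError("motif length must be >= 3")
        for i, col in enumerate(self.columns):
            if abs(sum(col.values()) - 1.0) > 1e-9:
                raise ValueError(f"motif column {i + 1} does not sum to 1")

    @property
    def length(self) -> int:
        return len(self.columns)

    def sample(self, rng: np.random.Generator) -> str:
        out = []
        for col in self.columns:
            letters = sorted(col)
            probs = np.array([col[le] for le in letters])
            out.append(letters[rng.choice(len(letters), p=probs / probs.sum())])
        return "".join(out)


def signal_peptide_motif(n_hydrophobic: int = 10) -> MotifSpec:
    """Met + one basic residue + a hydrophobic run; cleavage at the motif end."""
    hydro = {"L": 0.35, "A": 0.2, "V": 0.15, "I": 0.15, "F": 0.15}
    cols = [{"M": 1.0}, {"K": 0.5, "R": 0.5}] + [dict(hydro)] * n_hydrophobic
    return MotifSpec(placement="Nterm", columns=cols, cleavage_at_end=True)


def pts1_motif() -> MotifSpec:
    """C-terminal tripeptide: SKL / SRL / SRM mixture."""
    return MotifSpec(
        placement="Cterm",
        columns=[{"S": 1.0}, {"K": 1 / 3, "R": 2 / 3}, {"L": 2 / 3, "M": 1 / 3}],
    )


def nls_motif(run: int = 5) -> MotifSpec:
    """Internal basic stretch: a run of lysines/arginines."""
    return MotifSpec(placement="internal", columns=[{"K": 0.7, "R": 0.3}] * run)


@dataclass
class ClassSpec:
    name: str
    organelle: str
    suborganelle: str
    motif: MotifSpec | None = None


@dataclass
class SimConfig:
    classes: list
    n_per_class: int = 150
    length_range: tuple = (80, 300)
    multi_label_fraction: float = 0.0
    lv1_only_fraction: float = 0.0
    background_freqs: dict = field(default_factory=lambda: dict(BACKGROUND_FREQS))
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.multi_label_fraction < 1.0):
            raise ValueError("multi_label_fraction must be in [0, 1)")
        if not (0.0 <= self.lv1_only_fraction < 1.0):
            raise ValueError("lv1_only_fraction must be in [0, 1)")
        total = sum(self.background_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("background letter frequencies must sum to 1")


def default_sim_config(seed: int = 0, n_per_class: int = 150) -> SimConfig:
    """The standard desk-scale study: three signal classes plus background."""
    return SimConfig(
        classes=[
            ClassSpec("nterm_signal", "mitochondrion", "mitochondrial matrix",
                      signal_peptide_motif()),
            ClassSpec("cterm_pts1", "peroxisome", "peroxisomal matrix",
                      pts1_motif()),
            ClassSpec("internal_nls", "nucleus", "nucleoplasm", nls_motif()),
            ClassSpec("background", "cytoplasm", "cytosol", None),
        ],
        n_per_class=n_per_class,
        seed=seed,
    )


def toy_hierarchy(cfg: SimConfig) -> LabelHierarchy:
    """A label hierarchy spanning exactly the classes of a SimConfig."""
    organelles: list = []
    entries = []
    for cls in cfg.classes:
        if cls.organelle not in organelles:
            organelles.append(cls.organelle)
        entries.append((cls.organelle, cls.suborganelle))
    grid = [[None] * len(organelles) for _ in range(8)]
    name_to_cell: dict = {}
    next_slot = {o: 0 for o in organelles}
    for org, sub in entries:
        if sub in name_to_cell:
            continue
        col = organelles.index(org)
        row = next_slot[org]
        next_slot[org] += 1
        grid[row][col] = sub
        name_to_cell[sub] = (row, col)
    return LabelHierarchy(organelles=organelles, grid=grid, name_to_cell=name_to_cell)


@dataclass
class MotifTruth:
    accession: str
    class_name: str
    start: int  # 1-based inclusive
    end: int


def _background(rng, n, letters, probs):
    return "".join(letters[i] for i in rng.choice(len(letters), size=n, p=probs))


def simulate_proteome(cfg: SimConfig):
    """Generate labelled protein records with planted motifs.

    Returns (records, truths) where truths is a list of MotifTruth giving
    the planted coordinates (1-based inclusive) of every motif. Multi-label
    proteins additionally carry the motif of a second class with a different
    placement; records chosen as organelle-only keep their labels at the
    organelle level exclusively.
    """
    rng = np.random.default_rng(cfg.seed)
    letters = sorted(cfg.background_freqs)
    probs = np.array([cfg.background_freqs[le] for le in letters])
    probs = probs / probs.sum()

    lo, hi = cfg.length_range
    min_needed = max(
        (cls.motif.length for cls in cfg.classes if cls.motif), default=3
    )
    if hi < min_needed + 10:
        raise ValueError("length range too short for the configured motifs")

    records, truths = [], []
    counter = 0
    for cls in cfg.classes:
        for _ in range(cfg.n_per_class):
            counter += 1
            acc = f"SYN{counter:05d}"
            L = int(rng.integers(lo, hi + 1))
            seq = list("M" + _background(rng, L - 1, letters, probs))
            org_labels = {cls.organelle}
            sub_labels = {cls.suborganelle}
            cleavage = None

            plant = [cls] if cls.motif else []
            if cls.motif and cfg.multi_label_fraction > 0 and (
                rng.random() < cfg.multi_label_fraction
            ):
                others = [
                    c for c in cfg.classes
                    if c.motif and c.motif.placement != cls.motif.placement
                ]
                if others:
                    extra = others[int(rng.integers(len(others)))]
                    plant.append(extra)
                    org_labels.add(extra.organelle)
                    sub_labels.add(extra.suborganelle)

            used = []  # occupied (start0, end0) spans, 0-based inclusive
            for p in plant:
                motif = p.motif.sample(rng)
                k = len(motif)
                if p.motif.placement == "Nterm":
                    s0 = 0
                elif p.motif.placement == "Cterm":
                    s0 = L - k
                else:  # internal: keep clear of termini and other motifs
                    margin = 15
                    for _attempt in range(100):
                        s0 = int(rng.integers(margin, L - k - margin + 1))
                        if all(s0 + k <= a or s0 >= b + 1 for a, b in used):
                            break
                    else:
                        raise RuntimeError("could not place internal motif")
                seq[s0 : s0 + k] = list(motif)
                used.append((s0, s0 + k - 1))
                truths.append(MotifTruth(acc, p.name, s0 + 1, s0 + k))
                if p.motif.placement == "Nterm" and p.motif.cleavage_at_end:
                    cleavage = k

            lv1_only = rng.random() < cfg.lv1_only_fraction
            records.append(
                ProteinRecord(
                    accession=acc,
                    sequence="".join(seq),
                    organelle_labels=org_labels,
                    suborganelle_labels=set() if lv1_only else sub_labels,
                    cleavage_site=cleavage,
                    created_year=int(2010 + rng.integers(0, 12)),
                    evidence_experimental=True,
                    existence_level="protein",
                    is_fragment=False,
                    organelle_encoded=False,
                )
            )
    return records, truths


def simulate_hits(train_records, test_records, overlaps, seed: int = 0):
    """Emit an alignment-hit table with planted, fully controlled statistics.

    `overlaps` is a list of (train_accession, test_accession, identity,
    coverage, evalue) tuples; coverage is relative to the shorter sequence.
    Returns (hits, expected_removed) where expected_removed applies the
    redundancy rule (coverage > 0.8 and (identity > 40 or E <= 1e-5)) to the
    planted values — the generator's ground truth for the filter.
    """
    train_len = {r.accession: len(r.sequence) for r in train_records}
    test_len = {r.accession: len(r.sequence) for r in test_records}
    hits, expected = [], set()
    for q, s, identity, coverage, evalue in overlaps:
        if q not in train_len or s not in test_len:
            raise ValueError(f"unknown pair ({q!r}, {s!r})")
        shorter = min(train_len[q], test_len[s])
        hits.append(
            AlignmentHit(
                query=q, subject=s, identity=float(identity),
                length=int(round(coverage * shorter)), evalue=float(evalue),
                qlen=train_len[q], slen=test_len[s],
            )
        )
        actual_cov = hits[-1].length / shorter
        if actual_cov > 0.8 and (identity > 40.0 or evalue <= 1e-5):
            expected.add(q)
    return hits, expected


def write_hits(hits, path) -> None:
    """BLAST outfmt-6 (std + qlen slen) table for the planted hits."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query, h.subject, f"{h.identity:.2f}", str(h.length),
                        "0", "0", "1", str(h.length), "1", str(h.length),
                        f"{h.evalue:.3g}", "0.0", str(h.qlen), str(h.slen),
                    ]
                )
                + "\n"
            )
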