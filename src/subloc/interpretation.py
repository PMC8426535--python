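"""Residue-level attention interpretation.

The attention matrix of a protein has one row per head, each a distribution
over sequence positions. Averaging over heads (and, for an ensemble, over
sub-models) gives a per-residue contribution profile in raw sequence
coordinates. Group-level analysis aligns profiles at a terminus or at the
annotated cleavage site and averages position-wise, together with
per-position residue frequencies for sequence-logo rendering. Because the
model attends more strongly near termini even on shuffled sequences, a
shuffle control re-runs the model on residue-permuted copies; the per-
position ratio of real to shuffled mean attention separates genuine sorting
signals (ratio well above 1) from terminus bias (ratio near 1).

High-attention segments (top-k residues with +/- flank windows, overlapping
windows merged) are exported as motif-discovery input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import AA_ORDER, EncodedProtein, blosum_fallback, encode, load_physchem
from .training import EnsembleModel

__all__ = [
    "AttentionProfile",
    "GroupProfile",
    "protein_attention",
    "terminus_profile",
    "cleavage_profile",
    "shuffle_control",
    "attention_ratio",
    "extract_segments",
    "write_profile_tsv",
    "write_segments_fasta",
    "write_logo_matrix",
    "plot_profile",
]


@dataclass
class AttentionProfile:
    """Head-averaged per-residue attention in raw coordinates."""

    positions: np.ndarray  # 1-based raw residue indices (encoded positions only)
    weights: np.ndarray  # same length; non-negative
    raw_length: int
    accession: str = ""
    per_head: np.ndarray | None = None  # (heads, n_positions), optional

    def weight_at(self, pos: int):
        """Attention at raw position `pos` (None for the unencoded middle)."""
        hit = np.nonzero(self.positions == pos)[0]
        return float(self.weights[hit[0]]) if hit.size else None

    @property
    def gap(self):
        """(start, end) of the unencoded middle of a truncated protein, in
        raw 1-based coordinates, or None when the whole sequence was
        encoded. Interpretation output is reported in raw coordinates, so
        the gap is annotated explicitly rather than silently stitched."""
        breaks = np.nonzero(np.diff(self.positions) > 1)[0]
        if breaks.size == 0:
            return None
        k = int(breaks[0])
        return (int(self.positions[k]) + 1, int(self.positions[k + 1]) - 1)


@dataclass
class GroupProfile:
    """Position-wise mean attention + residue frequencies for aligned proteins."""

    anchor: str  # "N" | "C" | "cleavage"
    offsets: np.ndarray  # aligned positions (anchor-relative for cleavage)
    mean_attention: np.ndarray  # NaN where no protein covers the position
    counts: np.ndarray  # proteins contributing per position
    frequencies: np.ndarray  # (n_positions, 20) letter frequencies, rows sum <= 1


def _models_of(ens):
    return ens.models if isinstance(ens, EnsembleModel) else [ens]


def protein_attention(ens, x: EncodedProtein) -> AttentionProfile:
    """Head-averaged (and ensemble-averaged) attention mapped to raw coordinates."""
    profiles, heads = [], []
    for model in _models_of(ens):
        _, A = model.predict(x.features[None], x.mask[None])
        A = A[0]  # (heads, L)
        heads.append(A[:, x.mask.astype(bool)])
        profiles.append(A.mean(axis=0))
    mean = np.mean(profiles, axis=0)
    valid = x.mask.astype(bool)
    return AttentionProfile(
        positions=x.origin_map[valid].copy(),
        weights=mean[valid],
        raw_length=x.raw_length,
        accession=x.accession,
        per_head=np.mean(heads, axis=0),
    )


def _aggregate(aligned):
    """aligned: list of (offsets array, weights array, letters list)."""
    all_offsets = sorted({int(o) for offs, _, _ in aligned for o in offs})
    index = {o: k for k, o in enumerate(all_offsets)}
    n = len(all_offsets)
    total = np.zeros(n)
    counts = np.zeros(n)
    freq = np.zeros((n, len(AA_ORDER)))
    aa_index = {a: j for j, a in enumerate(AA_ORDER)}
    for offs, weights, letters in aligned:
        for o, w, le in zip(offs, weights, letters):
            k = index[int(o)]
            total[k] += w
            counts[k] += 1
            j = aa_index.get(le.upper())
            if j is not None:
                freq[k, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
        freq = freq / np.maximum(counts, 1)[:, None]
    return np.array(all_offsets), mean, counts, freq


def terminus_profile(profiles, sequences, end: str = "N",
                     span: int = 50) -> GroupProfile:
    """Align the first (or last) `span` residues of each protein and average.

    Positions are 1..span counted from the chosen terminus. Proteins shorter
    than the span contribute the positions they have.
    """
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")
    aligned = []
    for prof, seq in zip(profiles, sequences):
        L = prof.raw_length
        if end == "N":
            sel = prof.positions <= span
            offs = prof.positions[sel]
        else:
            sel = prof.positions > L - span
            offs = L - prof.positions[sel] + 1  # 1 = last residue
        letters = [seq[p - 1] for p in prof.positions[sel]]
        aligned.append((offs, prof.weights[sel], letters))
    offsets, mean, counts, freq = _aggregate(aligned)
    return GroupProfile(anchor=end, offsets=offsets, mean_attention=mean,
                        counts=counts, frequencies=freq)


def cleavage_profile(profiles, records, before: int = 100,
                     after: int = 50) -> GroupProfile:
    """Align profiles at the annotated cleavage site (offset 0 = the site).

    Offsets run from -before to +after; positions outside a protein are
    missing for it. Records without a cleavage site are skipped with a
    warning (and excluded from the counts).
    """
    aligned, skipped = [], 0
    for prof, rec in zip(profiles, records):
        if rec.cleavage_site is None:
            skipped += 1
            continue
        site = rec.cleavage_site
        offs_raw = prof.positions - site
        sel = (offs_raw >= -before) & (offs_raw <= after)
        letters = [rec.sequence[p - 1] for p in prof.positions[sel]]
        aligned.append((offs_raw[sel], prof.weights[sel], letters))
    if skipped:
        warnings.warn(f"{skipped} record(s) without cleavage site skipped")
    if not aligned:
        raise ValueError("no records with a cleavage site")
    offsets, mean, counts, freq = _aggregate(aligned)
    return GroupProfile(anchor="cleavage", offsets=offsets, mean_attention=mean,
                        counts=counts, frequencies=freq)


def shuffle_control(ens, records, seed: int = 0, end: str = "N", span: int = 50,
                    physchem=None, normalize_profile: bool = True) -> GroupProfile:
    """Group profile of residue-shuffled copies of the records.

    Each sequence gets a seeded uniform permutation of its residues, is
    re-encoded (BLOSUM62 fallback profile) and re-run through the model; the
    shuffled profiles are aggregated exactly like `terminus_profile`.
    """
    if physchem is None:
        physchem = load_physchem()
    rng = np.random.default_rng(seed)
    cfg = _models_of(ens)[0].cfg
    profiles, sequences = [], []
    for rec in records:
        perm = rng.permutation(len(rec.sequence))
        shuffled = "".join(rec.sequence[i] for i in perm)
        prof = blosum_fallback(shuffled)
        x = encode(shuffled, prof, physchem,
                   normalize_profile=normalize_profile,
                   encode_length=cfg.encode_length)
        x.accession = rec.accession
        profiles.append(protein_attention(ens, x))
        sequences.append(shuffled)
    return terminus_profile(profiles, sequences, end=end, span=span)


def attention_ratio(real: GroupProfile, shuffled: GroupProfile,
                    floor: float = 1e-6):
    """Element-wise real/shuffled mean attention on the common positions.

    Returns (offsets, ratio) where the ratio is NaN at positions whose
    shuffled mean is below `floor` (flagged, not divided) or missing.
    """
    if real.anchor != shuffled.anchor:
        raise ValueError(
            f"anchor mismatch: {real.anchor!r} vs {shuffled.anchor!r}"
        )
    common = np.intersect1d(real.offsets, shuffled.offsets)
    ri = {int(o): k for k, o in enumerate(real.offsets)}
    si = {int(o): k for k, o in enumerate(shuffled.offsets)}
    ratio = np.full(len(common), np.nan)
    for k, o in enumerate(common):
        r = real.mean_attention[ri[int(o)]]
        s = shuffled.mean_attention[si[int(o)]]
        if np.isfinite(r) and np.isfinite(s) and s >= floor:
            ratio[k] = r / s
    return common, ratio


def extract_segments(profile: AttentionProfile, sequence: str, top_k: int = 5,
                     flank: int = 10):
    """Concatenate the windows around the top-k attention residues.

    Each selected residue expands to [i - flank, i + flank] clipped to the
    sequence; overlapping windows are merged; segments are joined by a
    spacer of 'X' of flank length. Ties in attention go to the smaller
    index. Returns (segment string, list of (start, end) 1-based inclusive).
    """
    order = sorted(
        range(len(profile.positions)),
        key=lambda k: (-profile.weights[k], profile.positions[k]),
    )[: min(top_k, len(profile.positions))]
    L = len(sequence)
    windows = sorted(
        (max(1, int(profile.positions[k]) - flank),
         min(L, int(profile.positions[k]) + flank))
        for k in order
    )
    merged = []
    for start, end in windows:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    spacer = "X" * flank
    segment = spacer.join(sequence[s - 1 : e] for s, e in merged)
    return segment, merged


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_profile_tsv(group: GroupProfile, path) -> None:
    """TSV: position, contributing proteins, mean attention, letter freqs."""
    with open(path, "w") as fh:
        fh.write("position\tcount\tmean_attention\t"
                 + "\t".join(AA_ORDER) + "\n")
        for k, o in enumerate(group.offsets):
            m = group.mean_attention[k]
            fh.write(
                f"{int(o)}\t{int(group.counts[k])}\t"
                + ("NA" if not np.isfinite(m) else f"{m:.6g}")
                + "\t"
                + "\t".join(f"{v:.4f}" for v in group.frequencies[k])
                + "\n"
            )


#: motif-discovery parameter hints written beside the segment FASTA
GLAM2_HINTS = {"initial_columns": 15, "maximum_columns": 30}


def write_segments_fasta(segments, path, hints_path=None) -> None:
    """Segments (accession -> segment string) as FASTA plus a parameter sidecar."""
    with open(path, "w") as fh:
        for acc, seg in segments.items():
            fh.write(f">{acc}\n{seg}\n")
    if hints_path is not None:
        with open(hints_path, "w") as fh:
            for key, val in GLAM2_HINTS.items():
                fh.write(f"{key}\t{val}\n")


def write_logo_matrix(group: GroupProfile, path) -> None:
    """Sequence-logo-ready matrix: per position, letter frequency x attention."""
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(AA_ORDER) + "\n")
        for k, o in enumerate(group.offsets):
            m = group.mean_attention[k]
            w = m if np.isfinite(m) else 0.0
            fh.write(
                f"{int(o)}\t"
                + "\t".join(f"{v * w:.6g}" for v in group.frequencies[k])
                + "\n"
            )


def plot_profile(profile, path, highlight=None) -> None:
    """Minimal per-protein attention plot (position vs weight)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(profile.positions, profile.weights, lw=0.8)
    if highlight is not None:
        ax.axvspan(highlight[0], highlight[1], color="peachpuff", alpha=0.6)
    ax.set_xlabel("sequence position")
    ax.set_ylabel("attention")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
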