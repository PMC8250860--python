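"""Literal short-motif scanning and small multiple sequence alignments.

Motif patterns are ordered residue constraints: an uppercase one-letter
amino-acid code fixes the residue, a lowercase ``x`` matches any of the 20
standard residues (never a gap, never the unknown letter X). Built-ins
cover the c-di-GMP binding motifs RxxD / RxxxR and the glycosyltransferase
motifs QxxRW / DxD / TED. All occurrences are reported, overlapping ones
included.

The MSA here is a center-star construction: the center sequence maximizes
the summed pairwise alignment score; every other sequence is aligned to
the center pairwise and gaps are merged by "once a gap, always a gap".
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import ScoringScheme, align_pair, aligned_strings, blosum62

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str   # e.g. "RxxD": uppercase fixed, lowercase x wildcard

    def __post_init__(self):
        for c in self.pattern:
            if c != "x" and (not c.isupper() or c not in _STANDARD):
                raise ValueError(
                    f"bad constraint {c!r} in pattern {self.pattern!r}: "
                    "use an uppercase standard residue or 'x'"
                )

    def __len__(self) -> int:
        return len(self.pattern)

    def matches_at(self, seq: str, i: int) -> bool:
        if i + len(self.pattern) > len(seq):
            return False
        for c, s in zip(self.pattern, seq[i:i + len(self.pattern)]):
            if c == "x":
                if s not in _STANDARD:
                    return False
            elif s != c:
                return False
        return True

    @classmethod
    def from_string(cls, pattern: str, name: str | None = None) -> "MotifPattern":
        return cls(name=name or pattern, pattern=pattern)


BUILTIN_MOTIFS = (
    MotifPattern("RxxD", "RxxD"),
    MotifPattern("RxxxR", "RxxxR"),
    MotifPattern("QxxRW", "QxxRW"),
    MotifPattern("DxD", "DxD"),
    MotifPattern("TED", "TED"),
)


@dataclass(frozen=True)
class MotifHit:
    """1-based inclusive residue positions on the ungapped sequence."""

    protein_id: str
    motif: str
    start: int
    end: int
    matched: str


def scan_motifs(
    seq: str,
    patterns: list[MotifPattern] = BUILTIN_MOTIFS,
    protein_id: str = "",
) -> list[MotifHit]:
    """All (overlapping) motif occurrences, sorted by start then motif name."""
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    hits = []
    for pat in patterns:
        for i in range(len(seq) - len(pat) + 1):
            if pat.matches_at(seq, i):
                hits.append(MotifHit(
                    protein_id=protein_id, motif=pat.name,
                    start=i + 1, end=i + len(pat),
                    matched=seq[i:i + len(pat)],
                ))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def write_motif_report(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tmotif\tstart\tend\tmatched\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.motif}\t{h.start}\t{h.end}\t{h.matched}\n")


# ---------------------------------------------------------------------------
# center-star MSA
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def center_star_msa(
    seqs: list[str],
    ids: list[str] | None = None,
    scheme: ScoringScheme | None = None,
) -> MSA:
    """Center-star multiple alignment ("once a gap, always a gap").

    The center is the input maximizing its summed pairwise alignment score
    against all others (ties: first index). Row order follows the input.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    scheme = scheme or blosum62()
    ids = ids or [f"seq{i + 1}" for i in range(len(seqs))]
    k = len(seqs)

    # end gaps are charged here (true global alignment): homologous inputs
    # should align over their full length, and the center-star cost bound
    # only holds for a metric-like pairwise distance
    totals = [0.0] * k
    for i in range(k):
        for j in range(i + 1, k):
            s = align_pair(seqs[i], seqs[j], scheme, free_ends=False).score
            totals[i] += s
            totals[j] += s
    center = max(range(k), key=lambda i: (totals[i], -i))
    cseq = seqs[center]
    L = len(cseq)

    # For each non-center sequence, place its residues relative to the
    # center: placement[p] = center slot of residue p, where slot s in
    # [0, L] means "in the gap region before center residue s" (s == L is
    # the tail), and aligned residues record (slot, True).
    placements = []
    for i in range(k):
        if i == center:
            placements.append(None)
            continue
        row_c, row_o = aligned_strings(cseq, seqs[i], scheme, free_ends=False)
        place: list[tuple[int, bool]] = []
        cpos = 0
        for cc, oc in zip(row_c, row_o):
            if cc != "-" and oc != "-":
                place.append((cpos, True))
                cpos += 1
            elif cc != "-":
                cpos += 1
            elif oc != "-":
                place.append((cpos, False))
        placements.append(place)

    # gap budget per slot = max insertions any sequence needs there
    ins = [0] * (L + 1)
    for place in placements:
        if place is None:
            continue
        count = [0] * (L + 1)
        for slot, aligned in place:
            if not aligned:
                count[slot] += 1
        for s in range(L + 1):
            ins[s] = max(ins[s], count[s])

    # column layout: [ins[0] gap columns][center 0][ins[1]][center 1] ...
    col_of_center = [0] * L
    acc = 0
    for s in range(L):
        acc += ins[s]
        col_of_center[s] = acc
        acc += 1
    ncols = acc + ins[L]

    rows = []
    for i in range(k):
        if i == center:
            row = ["-"] * ncols
            for s, ch in enumerate(cseq):
                row[col_of_center[s]] = ch
            rows.append("".join(row))
            continue
        row = ["-"] * ncols
        place = placements[i]
        seq = seqs[i]
        used = [0] * (L + 1)  # insertions consumed per slot (left-aligned)
        for p, (slot, aligned) in enumerate(place):
            if aligned:
                col = col_of_center[slot]
            else:
                base = (col_of_center[slot] - ins[slot]) if slot < L \
                    else ncols - ins[L]
                col = base + used[slot]
                used[slot] += 1
            row[col] = seq[p]
        rows.append("".join(row))
    return MSA(ids=list(ids), rows=rows)


def identical_columns(msa: MSA) -> tuple[int, list[int]]:
    """Columns (1-based) where all rows carry the same residue, no gaps."""
    positions = []
    for c in range(msa.ncols):
        col = {row[c] for row in msa.rows}
        if len(col) == 1 and "-" not in col:
            positions.append(c + 1)
    return len(positions), positions


def msa_column_of(msa: MSA, row_index: int, residue_pos: int) -> int:
    """Map a 1-based ungapped residue position to its 1-based MSA column."""
    seen = 0
    for c, ch in enumerate(msa.rows[row_index]):
        if ch != "-":
            seen += 1
            if seen == residue_pos:
                return c + 1
    raise IndexError(f"residue position {residue_pos} beyond row {row_index}")


def sum_of_pairs_score(msa: MSA, scheme: ScoringScheme | None = None,
                       gap_col_score: float | None = None) -> float:
    """Sum-of-pairs column score of an MSA under a simple scheme.

    Residue pairs score by the substitution matrix; residue-vs-gap pairs
    score ``gap_col_score`` (default: -gap_extend); gap-vs-gap pairs score
    0. Used by tests to compare against exhaustive multi-way alignment.
    """
    from .align import encode

    scheme = scheme or blosum62()
    if gap_col_score is None:
        gap_col_score = -scheme.gap_extend
    total = 0.0
    # per-row column codes with -1 for gaps
    mats = []
    for r in msa.rows:
        vals, p = [], 0
        enc = encode(r.replace("-", ""))
        for ch in r:
            if ch == "-":
                vals.append(-1)
            else:
                vals.append(int(enc[p]))
                p += 1
        mats.append(vals)
    nrows = len(mats)
    for c in range(msa.ncols):
        for i in range(nrows):
            for j in range(i + 1, nrows):
                a, b = mats[i][c], mats[j][c]
                if a >= 0 and b >= 0:
                    total += scheme.matrix[a, b]
                elif a >= 0 or b >= 0:
                    total += gap_col_score
    return total
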