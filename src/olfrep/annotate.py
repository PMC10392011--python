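"""Receptor gene-model annotation from genome assemblies.

The stage chain mirrors classical homology-based receptor annotation:

1. six-frame translated search of reference receptor proteins against the
   genome (seed-and-extend local alignment, BLOSUM62);
2. best-query resolution of overlapping hits;
3. chaining of high-scoring pairs (HSPs) from different parts of the same
   query, with family-specific intron caps (10 kb for OR/TAAR/V1R, 30 kb
   for V2R);
4. extraction of the candidate region with 3 kb flanks;
5. open-reading-frame recovery and the 275 aa (OR/TAAR/V1R) / 700 aa (V2R)
   intact-length filter;
6. decoy-aware family and subtype classification by global alignment;
7. iteration of the whole chain with accepted models added to the search
   references, to pull in diverged, unannotated receptors.

Coordinates are 0-based half-open internally; GFF3 output is converted at
the I/O boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from ._align import (
    blosum62_lookup,
    global_score,
    percent_identity,
    reverse_complement,
    translate,
)
from .simulate import DECOY_FAMILY, FAMILIES, RefProtein, references_by_family

#: intact-model minimum protein length per family
MIN_PROTEIN_LENGTH = {"OR": 275, "TAAR": 275, "V1R": 275, "V2R": 700}
#: maximum intron size accepted when chaining HSPs of one query
MAX_INTRON = {"OR": 10_000, "TAAR": 10_000, "V1R": 10_000, "V2R": 30_000}

#: smallest genomic gap chained as an intron; HSP pairs split by less than
#: this (e.g. around an in-frame premature stop) are not spliced together,
#: so pseudogene fragments cannot be rescued into a fake intact model
MIN_INTRON = 50

DEFAULT_FLANK = 3_000
DEFAULT_SEARCH_MIN_SCORE = 120.0
DEFAULT_CLASSIFY_MIN_SCORE = 150.0
MIN_CLASSIFY_IDENTITY = 35.0  # best non-decoy identity below this rejects

_WORD = 4
_TWO_HIT_WINDOW = 40
_XDROP = 25
#: amino acids overlapping on the query tolerated between chained HSPs
#: (ungapped extension overruns exon boundaries by a few residues)
_CHAIN_QUERY_OVERLAP = 15


class EmptyGenomeError(ValueError):
    pass


class ReferenceAlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class Hsp:
    """A high-scoring segment pair between a query protein and the genome."""

    query_id: str
    query_family: str
    scaffold: str
    target_start: int  # bp, 0-based half-open, forward-strand coordinates
    target_end: int
    strand: str
    query_start: int  # aa positions on the query, half-open
    query_end: int
    score: float
    frame: int

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise ValueError("target_start must be < target_end")
        if self.score <= 0:
            raise ValueError("HSP score must be positive")


@dataclass(frozen=True)
class DraftModel:
    query_id: str
    family: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, ascending
    query_spans: tuple[tuple[int, int], ...]  # aa spans matching exons
    score: float

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    id: str
    family: str
    subtype: str | None
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein: str
    status: str = "intact"
    score: float = 0.0

    @property
    def intact(self) -> bool:
        return self.status == "intact"


@dataclass(frozen=True)
class AssemblyStats:
    scaffold_lengths: tuple[int, ...]
    busco_completeness: float
    polypteriform: bool = False
    lineage_wgd: bool = False

    @property
    def genome_length(self) -> int:
        return sum(self.scaffold_lengths)

    @property
    def n50(self) -> int:
        return compute_n50(self.scaffold_lengths)


@dataclass(frozen=True)
class QcReport:
    n50_ratio_pass: bool
    busco_pass: bool
    or_scaffold_dispersion_pass: bool

    @property
    def overall_pass(self) -> bool:
        return (
            self.n50_ratio_pass
            and self.busco_pass
            and self.or_scaffold_dispersion_pass
        )


# ---------------------------------------------------------------------------
# translated search


def _encode(protein: str) -> np.ndarray:
    return np.frombuffer(protein.encode(), dtype=np.uint8) & 31


def _words(codes: np.ndarray) -> np.ndarray:
    if len(codes) < _WORD:
        return np.empty(0, dtype=np.int64)
    w = codes.astype(np.int64)
    return (w[:-3] << 15) | (w[1:-2] << 10) | (w[2:-1] << 5) | w[3:]


def _extend(
    qcodes: np.ndarray,
    tcodes: np.ndarray,
    qpos: int,
    tpos: int,
    lut: np.ndarray,
    stop_code: int,
) -> tuple[int, int, int, int, float]:
    """Ungapped X-drop extension around a seed word on one diagonal.

    Extension never crosses a stop codon in the translated frame. Returns
    (query_start, query_end, target_start, target_end, score) in aa units.
    """
    # right extension (seed included)
    best = 0
    score = 0
    best_right = qpos
    i, j = qpos, tpos
    while i < len(qcodes) and j < len(tcodes):
        if tcodes[j] == stop_code:
            break
        score += lut[qcodes[i], tcodes[j]]
        if score > best:
            best, best_right = score, i + 1
        if score < best - _XDROP:
            break
        i += 1
        j += 1
    total = best
    # left extension
    best = 0
    score = 0
    best_left = qpos
    i, j = qpos - 1, tpos - 1
    while i >= 0 and j >= 0:
        if tcodes[j] == stop_code:
            break
        score += lut[qcodes[i], tcodes[j]]
        if score > best:
            best, best_left = score, i
        if score < best - _XDROP:
            break
        i -= 1
        j -= 1
    total += best
    offset = tpos - qpos
    return best_left, best_right, best_left + offset, best_right + offset, float(total)


def _frame_to_genomic(
    aa_start: int, aa_end: int, frame: int, strand: str, scaffold_len: int
) -> tuple[int, int]:
    if strand == "+":
        return frame + 3 * aa_start, frame + 3 * aa_end
    return scaffold_len - frame - 3 * aa_end, scaffold_len - frame - 3 * aa_start


def translated_search(
    genome: dict[str, str],
    references: list[RefProtein],
    min_score: float = DEFAULT_SEARCH_MIN_SCORE,
) -> list[Hsp]:
    """Six-frame seed-and-extend search of reference proteins in a genome.

    Exact 4-aa word seeds, two seeds on a diagonal within 40 aa trigger an
    ungapped BLOSUM62 X-drop extension; HSPs scoring >= ``min_score`` are
    reported with genomic coordinates on the matching strand.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise EmptyGenomeError("genome has no sequence")
    queries = [r for r in references if r.family != DECOY_FAMILY]
    if not queries:
        raise ValueError("no non-decoy reference proteins supplied")
    valid = set("ACDEFGHIKLMNPQRSTVWYXBZU*")
    for ref in queries:
        if not ref.seq or set(ref.seq) - valid:
            raise ReferenceAlphabetError(f"{ref.id} is not a protein sequence")

    lut = blosum62_lookup()
    stop_code = ord("*") & 31
    qcodes = [_encode(r.seq) for r in queries]
    word_index: dict[int, list[tuple[int, int]]] = {}
    for qi, codes in enumerate(qcodes):
        for qpos, word in enumerate(_words(codes)):
            word_index.setdefault(int(word), []).append((qi, qpos))
    query_words = np.fromiter(word_index.keys(), dtype=np.int64, count=len(word_index))

    hsps: list[Hsp] = []
    for scaffold, seq in genome.items():
        L = len(seq)
        for strand in "+-":
            strand_seq = seq if strand == "+" else reverse_complement(seq)
            for frame in range(3):
                prot = translate(strand_seq[frame:])
                tcodes = _encode(prot)
                words = _words(tcodes)
                if len(words) == 0:
                    continue
                hits_mask = np.isin(words, query_words)
                positions = np.nonzero(hits_mask)[0]
                if len(positions) == 0:
                    continue
                # gather (query, diagonal, position) triples, then two-hit
                qi_list, diag_list, pos_list = [], [], []
                for pos in positions:
                    for qi, qpos in word_index[int(words[pos])]:
                        qi_list.append(qi)
                        diag_list.append(int(pos) - qpos)
                        pos_list.append(int(pos))
                qi_arr = np.array(qi_list)
                diag_arr = np.array(diag_list)
                pos_arr = np.array(pos_list)
                order = np.lexsort((pos_arr, diag_arr, qi_arr))
                covered: dict[tuple[int, int], int] = {}
                prev_key: tuple[int, int] | None = None
                prev_pos = -(10**9)
                for k in order:
                    key = (int(qi_arr[k]), int(diag_arr[k]))
                    pos = int(pos_arr[k])
                    trigger = key == prev_key and 0 < pos - prev_pos <= _TWO_HIT_WINDOW
                    prev_key, prev_pos = key, pos
                    if not trigger:
                        continue
                    if covered.get(key, -1) >= pos:
                        continue
                    qi = key[0]
                    qpos = pos - key[1]
                    qs, qe, ts, te, score = _extend(
                        qcodes[qi], tcodes, qpos, pos, lut, stop_code
                    )
                    covered[key] = te
                    if score < min_score or qe <= qs:
                        continue
                    g_start, g_end = _frame_to_genomic(ts, te, frame, strand, L)
                    hsps.append(
                        Hsp(
                            query_id=queries[qi].id,
                            query_family=queries[qi].family,
                            scaffold=scaffold,
                            target_start=g_start,
                            target_end=g_end,
                            strand=strand,
                            query_start=qs,
                            query_end=qe,
                            score=score,
                            frame=frame,
                        )
                    )
    # drop exact duplicates (same locus reachable from several seeds)
    unique = {}
    for h in hsps:
        key = (h.query_id, h.scaffold, h.strand, h.target_start, h.target_end)
        if key not in unique or h.score > unique[key].score:
            unique[key] = h
    return sorted(
        unique.values(),
        key=lambda h: (h.scaffold, h.target_start, h.target_end, h.strand, h.query_id),
    )


# ---------------------------------------------------------------------------
# overlap resolution and chaining


def resolve_overlaps(hsps: list[Hsp]) -> list[Hsp]:
    """Keep, per overlap component, only the best query's HSPs.

    HSPs on the same scaffold and strand whose genomic intervals overlap
    form connected components; within each component the query with the
    highest summed score wins (ties broken by lexicographic query id).
    """
    kept: list[Hsp] = []
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.scaffold, h.strand), []).append(h)
    for members in groups.values():
        members.sort(key=lambda h: (h.target_start, h.target_end))
        component: list[Hsp] = []
        comp_end = -1
        for h in members + [None]:
            if h is not None and (not component or h.target_start < comp_end):
                component.append(h)
                comp_end = max(comp_end, h.target_end)
                continue
            if component:
                totals: dict[str, float] = {}
                for m in component:
                    totals[m.query_id] = totals.get(m.query_id, 0.0) + m.score
                best = min(totals, key=lambda q: (-totals[q], q))
                kept.extend(m for m in component if m.query_id == best)
            if h is not None:
                component = [h]
                comp_end = h.target_end
    return sorted(
        kept,
        key=lambda h: (h.scaffold, h.target_start, h.target_end, h.strand, h.query_id),
    )


def chain_hsps(hsps: list[Hsp], family: str | None = None) -> list[DraftModel]:
    """Chain HSPs of one query into draft gene models.

    HSPs sharing (query, scaffold, strand) are chained in genomic order when
    the genomic gap stays within the family's intron cap and query
    coordinates advance collinearly along the strand.
    """
    drafts: list[DraftModel] = []
    keyfn = lambda h: (h.query_id, h.scaffold, h.strand)
    for (query_id, scaffold, strand), group in itertools.groupby(
        sorted(hsps, key=keyfn), key=keyfn
    ):
        members = sorted(group, key=lambda h: h.target_start)
        fam = family or members[0].query_family
        cap = MAX_INTRON[fam] if fam in MAX_INTRON else MAX_INTRON["OR"]
        chain: list[Hsp] = []
        for h in members + [None]:
            if h is not None and chain:
                prev = chain[-1]
                gap = h.target_start - prev.target_end
                if strand == "+":
                    collinear = (
                        h.query_start >= prev.query_end - _CHAIN_QUERY_OVERLAP
                        and h.query_start > prev.query_start
                        and h.query_end > prev.query_end
                    )
                else:
                    collinear = (
                        h.query_end <= prev.query_start + _CHAIN_QUERY_OVERLAP
                        and h.query_end < prev.query_end
                        and h.query_start < prev.query_start
                    )
                if MIN_INTRON <= gap <= cap and collinear:
                    chain.append(h)
                    continue
            if chain:
                drafts.append(
                    DraftModel(
                        query_id=query_id,
                        family=fam,
                        scaffold=scaffold,
                        strand=strand,
                        exons=tuple((c.target_start, c.target_end) for c in chain),
                        query_spans=tuple(
                            (c.query_start, c.query_end) for c in chain
                        ),
                        score=sum(c.score for c in chain),
                    )
                )
            if h is not None:
                chain = [h]
    drafts.sort(key=lambda d: (d.scaffold, d.start, d.end, d.strand, d.query_id))
    return drafts


# ---------------------------------------------------------------------------
# region extraction and ORF recovery


def extract_region(
    draft: DraftModel, genome: dict[str, str], flank: int = DEFAULT_FLANK
) -> tuple[str, int]:
    """Genomic slice spanning the draft with flanks; returns (seq, offset).

    ``offset`` maps local coordinates back to the scaffold:
    global = local + offset.
    """
    seq = genome[draft.scaffold]
    start = max(0, draft.start - flank)
    end = min(len(seq), draft.end + flank)
    return seq[start:end], start


@dataclass(frozen=True)
class OrfResult:
    protein: str | None
    status: str  # intact | rejected:length | rejected:no_orf
    start: int = 0  # genomic span of the recovered CDS
    end: int = 0
    exons: tuple[tuple[int, int], ...] = ()


def _orfs_in_frame(prot: str):
    """(aa_start, aa_end_exclusive_of_stop) for every ATG..stop run."""
    orfs = []
    start = None
    for i, aa in enumerate(prot):
        if start is None and aa == "M":
            start = i
        elif aa == "*" and start is not None:
            orfs.append((start, i))
            start = None
    return orfs


def _local_exons(draft: DraftModel, offset: int, region_len: int):
    """Draft exons in model-strand local coordinates, 5'->3'."""
    exons = [(s - offset, e - offset) for s, e in draft.exons]
    spans = list(draft.query_spans)
    if draft.strand == "-":
        exons = [(region_len - e, region_len - s) for s, e in exons]
        exons.reverse()
        spans.reverse()
    return exons, spans


def find_orf(
    region: str,
    strand: str,
    draft: DraftModel,
    family: str,
    offset: int = 0,
) -> OrfResult:
    """Recover the coding sequence of a draft model from its region.

    Single-exon drafts take the longest ATG->stop ORF on the model strand
    that overlaps the homology segment. Multi-exon drafts are spliced at the
    HSP boundaries (trimming query-overlapping residues between adjacent
    segments), with the outer exons extended in frame to the nearest start
    and stop codons; the longest ORF inside the spliced translation is kept.
    The protein passes when it reaches 275 aa (OR/TAAR/V1R) or 700 aa (V2R).
    """
    min_len = MIN_PROTEIN_LENGTH.get(family, 275)
    local = region if strand == "+" else reverse_complement(region)
    n = len(local)
    exons, spans = _local_exons(draft, offset, n)

    if len(exons) == 1:
        anchor = exons[0]
        best: tuple[int, int, int] | None = None  # (length, frame, aa_start)
        for frame in range(3):
            prot = translate(local[frame:])
            for aa_s, aa_e in _orfs_in_frame(prot):
                s_local = frame + 3 * aa_s
                e_local = frame + 3 * aa_e
                if s_local < anchor[1] and anchor[0] < e_local:
                    length = aa_e - aa_s
                    if best is None or length > best[0]:
                        best = (length, frame, aa_s)
        if best is None:
            return OrfResult(None, "rejected:no_orf")
        length, frame, aa_s = best
        prot = translate(local[frame:])[aa_s: aa_s + length]
        s_local = frame + 3 * aa_s
        e_local = s_local + 3 * length + 3  # include stop codon in span
        if strand == "+":
            g_start, g_end = offset + s_local, offset + e_local
        else:
            g_start, g_end = offset + n - e_local, offset + n - s_local
        if length < min_len:
            return OrfResult(prot, "rejected:length", g_start, g_end,
                             ((g_start, g_end),))
        return OrfResult(prot, "intact", g_start, g_end, ((g_start, g_end),))

    # multi-exon: trim query overlaps, splice, extend outer boundaries
    segs: list[tuple[int, int]] = []
    for k, (exon, span) in enumerate(zip(exons, spans)):
        s, e = exon
        if k > 0:
            # spans are in model 5'->3' order here, ascending on the query
            # for both strands; X-drop overruns show up as query overlap
            overlap = max(0, spans[k - 1][1] - span[0])
            # trim the upstream segment's 3' end (already appended)
            if overlap:
                ps, pe = segs[-1]
                segs[-1] = (ps, max(ps, pe - 3 * overlap))
        segs.append((s, e))
    # extend first segment 5' in frame until a stop codon or region start
    s0, e0 = segs[0]
    while s0 - 3 >= 0 and local[s0 - 3: s0] not in ("TAA", "TAG", "TGA"):
        s0 -= 3
    segs[0] = (s0, e0)
    # extend last segment 3' in frame until just past a stop codon
    sl, el = segs[-1]
    while el + 3 <= n and local[el: el + 3] not in ("TAA", "TAG", "TGA"):
        el += 3
    el = min(el + 3, n - (n - el) % 3) if el + 3 <= n else el
    segs[-1] = (sl, el)
    spliced = "".join(local[s:e] for s, e in segs)
    prot_full = translate(spliced)
    orfs = _orfs_in_frame(prot_full)
    if not orfs:
        return OrfResult(None, "rejected:no_orf")
    aa_s, aa_e = max(orfs, key=lambda o: o[1] - o[0])
    prot = prot_full[aa_s:aa_e]

    # map spliced aa coordinates back to local exon coordinates
    def spliced_to_local(bp: int) -> int:
        for s, e in segs:
            if bp < e - s:
                return s + bp
            bp -= e - s
        return segs[-1][1]

    s_local = spliced_to_local(3 * aa_s)
    e_local = spliced_to_local(3 * aa_e + 2) + 1
    # clip exon segments to the ORF span
    clipped = []
    for s, e in segs:
        cs, ce = max(s, s_local), min(e, e_local)
        if cs < ce:
            clipped.append((cs, ce))
    if strand == "+":
        g_exons = tuple((offset + s, offset + e) for s, e in clipped)
    else:
        g_exons = tuple(
            sorted((offset + n - e, offset + n - s) for s, e in clipped)
        )
    g_start = min(s for s, _ in g_exons)
    g_end = max(e for _, e in g_exons)
    if len(prot) < min_len:
        return OrfResult(prot, "rejected:length", g_start, g_end, g_exons)
    return OrfResult(prot, "intact", g_start, g_end, g_exons)


# ---------------------------------------------------------------------------
# classification


def classify_family(
    protein: str,
    reference_db: list[RefProtein],
    min_score: float = DEFAULT_CLASSIFY_MIN_SCORE,
) -> tuple[str, str | None] | tuple[None, str]:
    """Assign a family (and subtype) by best global-alignment reference.

    Returns ``(family, subtype)`` on success, or ``(None, reason)`` where
    reason is ``non_olf`` (best hit is a decoy), ``low_score`` or
    ``low_identity`` (best non-decoy identity < 35%).
    """
    if not reference_db:
        raise ValueError("empty reference database")
    if not any(r.family == DECOY_FAMILY for r in reference_db):
        raise ValueError("reference database must contain a decoy family")
    best: RefProtein | None = None
    best_score = -np.inf
    for ref in sorted(reference_db, key=lambda r: r.id):
        score = global_score(protein, ref.seq)
        if score > best_score:
            best, best_score = ref, score
    assert best is not None
    if best.family == DECOY_FAMILY:
        return None, "non_olf"
    if best_score < min_score:
        return None, "low_score"
    if percent_identity(protein, best.seq) < MIN_CLASSIFY_IDENTITY:
        return None, "low_identity"
    return best.family, best.subtype


# ---------------------------------------------------------------------------
# iteration


def _overlaps(a: GeneModel | DraftModel, b: GeneModel, slack: int = 0) -> bool:
    return (
        a.scaffold == b.scaffold
        and a.strand == b.strand
        and a.start < b.end + slack
        and b.start < a.end + slack
    )


def annotate_once(
    genome: dict[str, str],
    search_refs: list[RefProtein],
    classify_refs: list[RefProtein],
    min_score: float = DEFAULT_SEARCH_MIN_SCORE,
    classify_min_score: float = DEFAULT_CLASSIFY_MIN_SCORE,
    flank: int = DEFAULT_FLANK,
    hsps: list[Hsp] | None = None,
) -> tuple[list[GeneModel], list[GeneModel]]:
    """One pass of search -> resolve -> chain -> extract -> ORF -> classify.

    ``hsps`` may supply externally computed hits in place of the built-in
    search. Returns (accepted intact models, rejected candidates).
    """
    if hsps is None:
        hsps = translated_search(genome, search_refs, min_score=min_score)
    hsps = resolve_overlaps(hsps)
    drafts = chain_hsps(hsps)

    accepted: list[GeneModel] = []
    rejected: list[GeneModel] = []
    # best draft per locus first, so duplicated queries do not duplicate loci
    drafts.sort(key=lambda d: (-d.score, d.scaffold, d.start, d.query_id))
    taken: list[DraftModel] = []
    unique_drafts = []
    for d in drafts:
        if any(
            d.scaffold == t.scaffold
            and d.strand == t.strand
            and d.start < t.end
            and t.start < d.end
            for t in taken
        ):
            continue
        taken.append(d)
        unique_drafts.append(d)
    for draft in sorted(unique_drafts, key=lambda d: (d.scaffold, d.start)):
        region, offset = extract_region(draft, genome, flank=flank)
        orf = find_orf(region, draft.strand, draft, draft.family, offset=offset)
        model_id = f"{draft.scaffold}:{draft.start}-{draft.end}{draft.strand}"
        if orf.status != "intact":
            rejected.append(
                GeneModel(
                    id=model_id,
                    family=draft.family,
                    subtype=None,
                    scaffold=draft.scaffold,
                    start=orf.start or draft.start,
                    end=orf.end or draft.end,
                    strand=draft.strand,
                    exons=orf.exons or draft.exons,
                    protein=orf.protein or "",
                    status=orf.status,
                    score=draft.score,
                )
            )
            continue
        family, subtype = classify_family(
            orf.protein, classify_refs, min_score=classify_min_score
        )
        if family is None:
            rejected.append(
                GeneModel(
                    id=model_id,
                    family=draft.family,
                    subtype=None,
                    scaffold=draft.scaffold,
                    start=orf.start,
                    end=orf.end,
                    strand=draft.strand,
                    exons=orf.exons,
                    protein=orf.protein,
                    status=f"rejected:{subtype}",
                    score=draft.score,
                )
            )
            continue
        accepted.append(
            GeneModel(
                id=model_id,
                family=family,
                subtype=subtype,
                scaffold=draft.scaffold,
                start=orf.start,
                end=orf.end,
                strand=draft.strand,
                exons=orf.exons,
                protein=orf.protein,
                status="intact",
                score=draft.score,
            )
        )
    return accepted, rejected


def iterate_annotation(
    genome: dict[str, str],
    references: list[RefProtein],
    min_score: float = DEFAULT_SEARCH_MIN_SCORE,
    classify_min_score: float = DEFAULT_CLASSIFY_MIN_SCORE,
    flank: int = DEFAULT_FLANK,
    max_iter: int = 5,
    hsps: list[Hsp] | None = None,
) -> tuple[list[GeneModel], dict]:
    """Iterative annotation to a fixed point (or ``max_iter``).

    Accepted models join the search reference set between rounds so that
    receptors too diverged from the initial references are recovered through
    intermediate homologs. Model identity is keyed on the genomic interval
    (scaffold, start, end, strand). Classification always uses the initial
    reference database (including decoys).
    """
    models: list[GeneModel] = []
    seen: set[tuple[str, int, int, str]] = set()
    search_refs = list(references)
    info = {"iterations": 0, "added_per_iteration": [], "rejected": []}
    for _round in range(max_iter):
        info["iterations"] += 1
        accepted, rejected = annotate_once(
            genome,
            search_refs,
            references,
            min_score=min_score,
            classify_min_score=classify_min_score,
            flank=flank,
            hsps=hsps if _round == 0 else None,
        )
        hsps = None  # external hits only seed the first round
        added = 0
        for model in accepted:
            key = (model.scaffold, model.start, model.end, model.strand)
            if key in seen:
                continue
            if any(_overlaps(model, m) for m in models):
                continue
            seen.add(key)
            models.append(model)
            search_refs.append(
                RefProtein(
                    f"model|{model.id}", model.family, model.subtype, model.protein
                )
            )
            added += 1
        info["added_per_iteration"].append(added)
        info["rejected"] = rejected
        if added == 0:
            break
    models.sort(key=lambda m: (m.scaffold, m.start, m.end))
    final = [
        replace(m, id=f"olf{(i + 1):04d}") for i, m in enumerate(models)
    ]
    return final, info


# ---------------------------------------------------------------------------
# assembly QC


def compute_n50(lengths) -> int:
    """Smallest length L such that sequences >= L sum to half the total."""
    lengths = [int(x) for x in lengths]
    if not lengths or any(x <= 0 for x in lengths):
        raise ValueError("n50 requires at least one positive length")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if acc >= total / 2:
            return x
    return min(lengths)


def qc_assembly(stats: AssemblyStats, models: list[GeneModel]) -> QcReport:
    """Apply the three assembly-quality filters.

    (i) N50 over genome length at least 10 Mb/Gb; (ii) BUSCO completeness
    at least 90% (85% tolerated for Polypteriformes); (iii) intact OR models
    on fewer than 20 scaffolds (up to 30 allowed with a lineage-specific
    whole-genome duplication).
    """
    ratio = stats.n50 / stats.genome_length  # both in bp: 10 Mb/Gb == 0.01
    n50_pass = ratio >= 0.01
    busco_floor = 0.85 if stats.polypteriform else 0.90
    busco_pass = stats.busco_completeness >= busco_floor
    or_scaffolds = len(
        {m.scaffold for m in models if m.family == "OR" and m.intact}
    )
    if stats.lineage_wgd:
        dispersion_pass = or_scaffolds <= 30
    else:
        dispersion_pass = or_scaffolds < 20
    return QcReport(n50_pass, busco_pass, dispersion_pass)


def family_counts(models: list[GeneModel]) -> dict[str, int]:
    counts = {fam: 0 for fam in FAMILIES}
    for m in models:
        if m.intact:
            counts[m.family] = counts.get(m.family, 0) + 1
    return counts


def subtype_proportions(models: list[GeneModel], family: str = "OR") -> dict[str, float]:
    """Share of each subtype over the family's intact repertoire."""
    fam_models = [m for m in models if m.intact and m.family == family]
    if not fam_models:
        return {}
    out: dict[str, float] = {}
    for m in fam_models:
        label = m.subtype or "unlabelled"
        out[label] = out.get(label, 0.0) + 1.0
    return {k: v / len(fam_models) for k, v in sorted(out.items())}
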