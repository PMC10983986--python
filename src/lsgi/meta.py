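"""Cross-sample integration: meta-programs and compositional entropy.

Retained per-sample NMF programs are clustered by top-50-gene overlap.
Each cluster starts from a founder — the program with the most partners
sharing more than 20 of their top 50 genes (at least two partners required)
— and grows greedily: the unassigned program with the largest overlap
against the cluster's current 50-gene signature joins, provided it shares
at least 20 genes; after every merge the signature is recomputed by
ranking genes on how many members carry them in their top 50 (ties by mean
loading, then gene name) and keeping the top 50.  Programs never absorbed
into any cluster are labeled Unclustered.

A meta-program's study / tumor-type specificity is scored by delta-Shannon
entropy: the entropy of its member-category composition minus the mean
entropy after shuffling category labels across the whole catalog (10 draws
by default).  Strongly negative values mean the meta-program draws from
fewer categories than chance.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CatalogEntry",
    "ProgramCatalog",
    "MetaProgram",
    "EntropyReport",
    "overlap_count",
    "find_founder",
    "grow_meta_program",
    "cluster_meta_programs",
    "delta_shannon_entropy",
    "entropy_report",
]

SIGNATURE_SIZE = 50


@dataclass(frozen=True)
class CatalogEntry:
    """One retained per-sample program: its top-gene list and labels."""

    sample: str
    program: str
    genes: tuple          # descending-loading order, <= 50 genes
    loadings: tuple
    study: Optional[str] = None
    tumor_type: Optional[str] = None

    @property
    def key(self):
        return (self.sample, self.program)

    def __post_init__(self):
        if len(self.genes) != len(self.loadings):
            raise ValueError("genes/loadings length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in {self.key}")
        if len(self.genes) > SIGNATURE_SIZE:
            raise ValueError(f"{self.key}: more than {SIGNATURE_SIZE} genes")


class ProgramCatalog:
    """Collection of per-sample programs, sorted by (sample, program)."""

    def __init__(self, entries: Sequence[CatalogEntry]):
        entries = sorted(entries, key=lambda e: e.key)
        keys = [e.key for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("(sample, program) pairs must be unique")
        self.entries = list(entries)
        self._by_key = {e.key: e for e in self.entries}

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, key):
        return self._by_key[key]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProgramCatalog":
        """Build from a long table: sample, program, rank, gene, loading
        [, study, tumor_type]."""
        entries = []
        for (sample, program), grp in df.groupby(["sample", "program"], sort=True):
            grp = grp.sort_values("rank")
            entries.append(CatalogEntry(
                sample=str(sample), program=str(program),
                genes=tuple(grp["gene"]),
                loadings=tuple(grp["loading"].astype(float)),
                study=str(grp["study"].iloc[0]) if "study" in grp else None,
                tumor_type=str(grp["tumor_type"].iloc[0]) if "tumor_type" in grp else None,
            ))
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "ProgramCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for r, (g, l) in enumerate(zip(e.genes, e.loadings), start=1):
                rows.append((e.sample, e.program, r, g, l, e.study, e.tumor_type))
        return pd.DataFrame(rows, columns=[
            "sample", "program", "rank", "gene", "loading", "study", "tumor_type",
        ])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class MetaProgram:
    """A cluster of per-sample programs with a 50-gene consensus signature.

    ``signature`` rows are (gene, support count, mean loading), ranked.
    """

    mp_id: str
    members: list                 # (sample, program) keys, join order
    signature: list               # [(gene, support, mean_loading), ...]
    founder: tuple

    @property
    def signature_genes(self) -> list:
        return [g for g, _, _ in self.signature]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a meta-program needs >= 2 members")


def overlap_count(genes_a, genes_b) -> int:
    """Size of the intersection of two gene lists."""
    return len(set(genes_a) & set(genes_b))


def find_founder(entries: Sequence[CatalogEntry], overlap_min: int = 21,
                 partner_min: int = 2) -> Optional[CatalogEntry]:
    """The program with the most high-overlap partners, or None.

    A partner shares at least ``overlap_min`` top genes (default 21, i.e.
    "over 20").  A founder needs at least ``partner_min`` partners.  Ties:
    larger total overlap with partners, then lexicographic (sample,
    program).
    """
    best = None
    best_rank = None
    gene_sets = {e.key: set(e.genes) for e in entries}
    for e in entries:
        n_partners = 0
        total = 0
        mine = gene_sets[e.key]
        for other in entries:
            if other.key == e.key:
                continue
            ov = len(mine & gene_sets[other.key])
            if ov >= overlap_min:
                n_partners += 1
                total += ov
        if n_partners >= partner_min:
            rank = (-n_partners, -total, e.key)
            if best_rank is None or rank < best_rank:
                best, best_rank = e, rank
    return best


def _recompute_signature(members: Sequence[CatalogEntry]) -> list:
    """Rank genes by member support, then mean loading, then name; top 50."""
    support: Counter = Counter()
    load_sum: Counter = Counter()
    for m in members:
        for g, l in zip(m.genes, m.loadings):
            support[g] += 1
            load_sum[g] += l
    scored = [
        (g, support[g], load_sum[g] / support[g]) for g in support
    ]
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return scored[:SIGNATURE_SIZE]


def grow_meta_program(founder: CatalogEntry, entries: Sequence[CatalogEntry],
                      overlap_min: int = 20, mp_id: str = "MP_1",
                      against: str = "signature") -> MetaProgram:
    """Grow a cluster from a founder by greedy top-overlap merging.

    At each step the unassigned program with the highest overlap against
    the current 50-gene signature joins if it shares at least
    ``overlap_min`` genes; the signature is then recomputed.  With
    ``against="founder"`` overlaps are taken against the founder's static
    top-50 instead of the evolving signature.

    Returns None when no program merges at all (a meta-program needs at
    least two members; this cannot happen for a genuine founder, whose
    partners always clear the merge threshold).
    """
    if against not in ("signature", "founder"):
        raise ValueError("against must be 'signature' or 'founder'")
    members = [founder]
    signature = _recompute_signature(members)
    pool = {e.key: e for e in entries if e.key != founder.key}
    while pool:
        ref = set(founder.genes) if against == "founder" else {g for g, _, _ in signature}
        scored = sorted(
            ((overlap_count(e.genes, ref), e.key) for e in pool.values()),
            key=lambda t: (-t[0], t[1]),
        )
        best_ov, best_key = scored[0]
        if best_ov < overlap_min:
            break
        members.append(pool.pop(best_key))
        signature = _recompute_signature(members)
    if len(members) < 2:
        return None
    return MetaProgram(
        mp_id=mp_id,
        members=[m.key for m in members],
        signature=signature,
        founder=founder.key,
    )


def cluster_meta_programs(catalog: ProgramCatalog,
                          founder_overlap_min: int = 21,
                          merge_overlap_min: int = 20,
                          partner_min: int = 2,
                          against: str = "signature"):
    """Partition the catalog into meta-programs plus an Unclustered set.

    Deterministic loop: find a founder among the unassigned programs, grow
    its cluster, remove the members, repeat until no founder qualifies.
    Meta-programs are numbered in creation order; the result is invariant
    to catalog input order because the catalog is kept sorted and all
    tie-breaks are lexicographic on (sample, program).

    Returns ``(meta_programs, unclustered_keys)``.
    """
    unassigned = list(catalog.entries)
    stranded = []  # founders that attract no member under a stricter merge gate
    mps = []
    while True:
        founder = find_founder(unassigned, overlap_min=founder_overlap_min,
                               partner_min=partner_min)
        if founder is None:
            break
        mp = grow_meta_program(founder, unassigned,
                               overlap_min=merge_overlap_min,
                               mp_id=f"MP_{len(mps) + 1}", against=against)
        if mp is None:
            stranded.append(founder)
            unassigned = [e for e in unassigned if e.key != founder.key]
            continue
        member_keys = set(mp.members)
        unassigned = [e for e in unassigned if e.key not in member_keys]
        mps.append(mp)
    unclustered = sorted(e.key for e in unassigned + stranded)
    return mps, unclustered


# ---------------------------------------------------------------------------
# compositional entropy
# ---------------------------------------------------------------------------

@dataclass
class EntropyReport:
    """Per-meta-program delta-Shannon entropy rows for one label scheme."""

    scheme: str
    rows: pd.DataFrame  # mp_id, n_members, entropy, mean_shuffled, sd_shuffled, delta


def _shannon(labels: Sequence) -> float:
    n = len(labels)
    counts = Counter(labels)
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def delta_shannon_entropy(mp: MetaProgram, catalog: ProgramCatalog,
                          scheme: str = "study", n_shuffle: int = 10,
                          seed: int = 0, variant: str = "delta") -> dict:
    """Composition entropy of a meta-program minus its shuffled-label mean.

    The real entropy is the (natural-log) Shannon entropy of the member
    fractions per category.  The null shuffles the category labels across
    ALL catalog programs (preserving global label frequencies) and
    recomputes the entropy over the same member slots; the mean over
    ``n_shuffle`` seeded draws is subtracted: delta = H_real - mean(H_null).
    ``variant="max_minus_real"`` reports mean(H_null) - H_real instead.
    """
    if scheme not in ("study", "tumor_type"):
        raise ValueError("scheme must be 'study' or 'tumor_type'")
    if variant not in ("delta", "max_minus_real"):
        raise ValueError("variant must be 'delta' or 'max_minus_real'")
    labels = [getattr(e, scheme) for e in catalog.entries]
    if any(l is None for l in labels):
        raise ValueError(f"catalog entries missing {scheme} labels")
    slot_of = {e.key: i for i, e in enumerate(catalog.entries)}
    slots = [slot_of[k] for k in mp.members]
    h_real = _shannon([labels[i] for i in slots])
    rng = np.random.default_rng(seed)
    h_null = []
    for _ in range(n_shuffle):
        perm = rng.permutation(len(labels))
        h_null.append(_shannon([labels[perm[i]] for i in slots]))
    mean_null = float(np.mean(h_null))
    sd_null = float(np.std(h_null, ddof=1)) if n_shuffle > 1 else 0.0
    delta = h_real - mean_null
    if variant == "max_minus_real":
        delta = mean_null - h_real
    return {
        "mp_id": mp.mp_id,
        "n_members": len(mp.members),
        "entropy": h_real,
        "mean_shuffled": mean_null,
        "sd_shuffled": sd_null,
        "delta": delta,
    }


def entropy_report(mps: Sequence[MetaProgram], catalog: ProgramCatalog,
                   scheme: str = "study", n_shuffle: int = 10,
                   seed: int = 0, variant: str = "delta") -> EntropyReport:
    rows = [
        delta_shannon_entropy(mp, catalog, scheme=scheme, n_shuffle=n_shuffle,
                              seed=seed + i, variant=variant)
        for i, mp in enumerate(mps)
    ]
    df = pd.DataFrame(rows, columns=[
        "mp_id", "n_members", "entropy", "mean_shuffled", "sd_shuffled", "delta",
    ])
    return EntropyReport(scheme=scheme, rows=df)


def write_meta_tables(mps: Sequence[MetaProgram], unclustered, outdir) -> None:
    """Write membership and signature TSVs for a meta-program run."""
    from pathlib import Path

    outdir = Path(outdir)
    memb = []
    for mp in mps:
        for s, p in mp.members:
            memb.append((mp.mp_id, s, p))
    for s, p in unclustered:
        memb.append(("Unclustered", s, p))
    pd.DataFrame(memb, columns=["mp_id", "sample", "program"]).to_csv(
        outdir / "mp_membership.tsv", sep="\t", index=False)
    sig = []
    for mp in mps:
        for r, (g, sup, ml) in enumerate(mp.signature, start=1):
            sig.append((mp.mp_id, r, g, sup, ml))
    pd.DataFrame(sig, columns=["mp_id", "rank", "gene", "support", "mean_loading"]).to_csv(
        outdir / "mp_signatures.tsv", sep="\t", index=False, float_format="%.6g")
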