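"""Standard-format I/O and library-size normalization.

Internal coordinates are uniformly 0-based half-open; conversion to the
1-based inclusive GFF3 convention happens only at file boundaries.
Coverage tracks are strand-specific: one :class:`CoverageTrack` carries
exactly one strand and is never implicitly mixed with the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: scale constant for library-size normalization (reads per million)
RPM_SCALE = 1e6


class FormatError(ValueError):
    """Malformed input file."""


class NonContiguousGeneError(ValueError):
    """UTRs that do not abut the CDS on the correct sides."""


@dataclass
class CoverageTrack:
    """Per-nucleotide read coverage for one strand of one replicon.

    ``values[i]`` is the coverage (reads/nt, or normalized units) at
    0-based position ``i``.  ``library_total`` is the total number of
    mapped reads in the library the track came from and is shared by
    the two strand tracks of one library.
    """

    replicon_id: str
    strand: str
    values: np.ndarray
    library_total: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if not self.library_total > 0:
            raise ValueError("library_total must be > 0")

    def __len__(self) -> int:
        return self.values.shape[0]


def normalize_by_library_size(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw track to reads-per-million of its library.

    Each value is multiplied by ``1e6 / library_total``.  The particular
    constant cancels in every downstream ratio; RPM is used for
    readability.  Normalizing twice is an error.
    """
    if track.normalized:
        raise ValueError("track is already normalized")
    return replace(
        track,
        values=track.values * (RPM_SCALE / track.library_total),
        normalized=True,
    )


@dataclass(frozen=True)
class GeneModel:
    """One gene's strand, CDS and optional UTR extents (0-based half-open).

    The scanning footprint is the contiguous union of the 5'UTR, CDS and
    3'UTR.  On the minus strand the 5'UTR lies at higher genomic
    coordinates than the CDS.
    """

    id: str
    replicon_id: str
    strand: str
    cds: tuple[int, int]
    utr5: Optional[tuple[int, int]] = None
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        for iv in (self.cds, self.utr5, self.utr3):
            if iv is not None and not (0 <= iv[0] < iv[1]):
                raise ValueError(f"bad interval {iv} for gene {self.id}")
        # UTRs must abut the CDS on the biologically correct side
        left, right = (self.utr5, self.utr3) if self.strand == "+" else (self.utr3, self.utr5)
        if left is not None and left[1] != self.cds[0]:
            raise NonContiguousGeneError(
                f"gene {self.id}: upstream UTR {left} does not abut CDS {self.cds}"
            )
        if right is not None and right[0] != self.cds[1]:
            raise NonContiguousGeneError(
                f"gene {self.id}: downstream UTR {right} does not abut CDS {self.cds}"
            )

    @property
    def footprint(self) -> tuple[int, int]:
        start = self.cds[0]
        end = self.cds[1]
        for iv in (self.utr5, self.utr3):
            if iv is not None:
                start = min(start, iv[0])
                end = max(end, iv[1])
        return (start, end)

    @property
    def footprint_length(self) -> int:
        s, e = self.footprint
        return e - s


@dataclass(frozen=True)
class EndSite:
    """A mapped transcript terminus (0-based position of the end nucleotide)."""

    replicon_id: str
    strand: str
    position: int
    kind: str  # "five_prime" | "three_prime"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in ("five_prime", "three_prime"):
            raise ValueError(f"bad end-site kind {self.kind!r}")


@dataclass
class DecayExperiment:
    """Ordered time points x replicates of strand-specific coverage tracks.

    ``tracks[(t_index, replicate, strand)]`` holds one
    :class:`CoverageTrack`; replicates are numbered from 0.
    """

    replicon_id: str
    timepoints: tuple[float, ...]
    n_replicates: int
    tracks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing with >= 2 points")
        if tps[0] != 0.0:
            raise ValueError("first timepoint must be 0 (steady state)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        self.timepoints = tps

    def track(self, t_index: int, replicate: int, strand: str) -> CoverageTrack:
        return self.tracks[(t_index, replicate, strand)]

    def normalized(self) -> "DecayExperiment":
        """Return a copy with every track library-size normalized."""
        out = DecayExperiment(self.replicon_id, self.timepoints, self.n_replicates)
        out.tracks = {k: normalize_by_library_size(v) for k, v in self.tracks.items()}
        return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(
    path,
    replicon_length: int,
    strand: str,
    library_total: Optional[float] = None,
    replicon_id: Optional[str] = None,
    library_sizes: Optional[dict] = None,
    library_id: Optional[str] = None,
) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a dense track.

    Positions absent from the file are 0.  Overlapping intervals with
    conflicting values are an error.  ``library_total`` may be given
    directly or looked up as ``library_sizes[library_id]``.
    """
    if library_total is None:
        if library_sizes is None or library_id is None:
            raise ValueError("provide library_total or (library_sizes, library_id)")
        library_total = library_sizes[library_id]
    values = np.zeros(replicon_length, dtype=float)
    assigned = np.zeros(replicon_length, dtype=bool)
    seen_id = replicon_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if seen_id is None:
                seen_id = chrom
            elif chrom != seen_id:
                raise FormatError(f"{path}:{lineno}: multiple replicons ({chrom} vs {seen_id})")
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage value {v}")
            if not (0 <= s < e <= replicon_length):
                raise FormatError(f"{path}:{lineno}: interval [{s},{e}) outside replicon")
            seg = slice(s, e)
            conflict = assigned[seg] & (values[seg] != v)
            if conflict.any():
                raise FormatError(f"{path}:{lineno}: overlapping intervals with conflicting values")
            values[seg] = v
            assigned[seg] = True
    if seen_id is None:
        raise FormatError(f"{path}: empty bedGraph and no replicon_id given")
    return CoverageTrack(seen_id, strand, values, library_total)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as a bedGraph, omitting zero runs (read_bedgraph restores them)."""
    v = track.values
    with open(path, "w") as fh:
        if len(v) == 0:
            return
        # run-length encode
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        for s, e in zip(starts, ends):
            val = float(v[s])
            if val != 0:
                fh.write(f"{track.replicon_id}\t{s}\t{e}\t{val!r}\n")


def read_library_sizes(path) -> dict:
    """Read the ``library_sizes.tsv`` sidecar: library_id <tab> mapped reads."""
    df = pd.read_csv(path, sep="\t", header=None, names=["library_id", "total"], comment="#")
    return dict(zip(df["library_id"].astype(str), df["total"].astype(float)))


def write_library_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in sizes.items():
            fh.write(f"{k}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA into ``{record_id: sequence string}``."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = ("five_prime_UTR", "5'UTR", "five_prime_utr")
_UTR3_TYPES = ("three_prime_UTR", "3'UTR", "three_prime_utr")


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/CDS/UTR features into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open.  Genes without a CDS child are skipped with a warning;
    UTRs that do not abut the CDS raise :class:`NonContiguousGeneError`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        cds_iv = None
        utr5_iv = None
        utr3_iv = None
        for child in db.children(g.id):
            iv = (child.start - 1, child.end)
            if iv[0] < 0 or iv[1] <= iv[0]:
                raise FormatError(f"malformed coordinates on feature {child.id}")
            if child.featuretype == "CDS":
                cds_iv = iv if cds_iv is None else (min(cds_iv[0], iv[0]), max(cds_iv[1], iv[1]))
            elif child.featuretype in _UTR5_TYPES:
                utr5_iv = iv
            elif child.featuretype in _UTR3_TYPES:
                utr3_iv = iv
        if cds_iv is None:
            warnings.warn(f"gene {g.id} has no CDS; skipped", stacklevel=2)
            continue
        genes.append(
            GeneModel(
                id=g.id,
                replicon_id=g.seqid,
                strand=g.strand,
                cds=cds_iv,
                utr5=utr5_iv,
                utr3=utr3_iv,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write GeneModels as GFF3 (gene + CDS + UTR features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fs, fe = g.footprint
            fh.write(
                f"{g.replicon_id}\tdecarve\tgene\t{fs + 1}\t{fe}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            def feat(ftype, iv):
                fh.write(
                    f"{g.replicon_id}\tdecarve\t{ftype}\t{iv[0] + 1}\t{iv[1]}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.{ftype};Parent={g.id}\n"
                )
            if g.utr5 is not None:
                feat("five_prime_UTR", g.utr5)
            feat("CDS", g.cds)
            if g.utr3 is not None:
                feat("three_prime_UTR", g.utr3)


# ---------------------------------------------------------------------------
# End sites
# ---------------------------------------------------------------------------

def read_end_sites(path) -> list[EndSite]:
    """Read mapped transcript termini: replicon_id, strand, position, kind (TSV)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["replicon_id", "strand", "position", "kind"], comment="#",
    )
    return [
        EndSite(str(r.replicon_id), str(r.strand), int(r.position), str(r.kind))
        for r in df.itertuples()
    ]


def write_end_sites(sites: Iterable[EndSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.replicon_id}\t{s.strand}\t{s.position}\t{s.kind}\n")
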