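"""In-silico enzymatic construction of the LEGO shRNA library.

The chain simulated symbolically: AluI digestion (blunt AG^CT cuts),
adapter-A ligation at the cut 5' ends, MmeI capture of 18 bp + 2-nt overhang
of cDNA next to each adapter, ligation of the looped adapter C, nicking,
Klenow extension into a perfect inverted repeat, and BpmI release of the
insert at the restored AluI junctions. Because adapters ligate at both AluI
ends of every fragment, each AluI site can give rise to two shRNA vectors —
one from each flanking fragment, on opposite strands, both reading away
from the cut and therefore both starting with CT. The vector G preceding
the insert reconstitutes part of the AluI site, so transcribed hairpins
start with GCT.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .config import Config, DEFAULT_LOOP
from .errors import ConfigurationError, ValidationError
from .io import Transcript, reverse_complement

_ALUI = re.compile(r"(?=AGCT)")  # overlapping scan

#: Synthetic double-stranded half of the adapter-C center retained in the
#: 91-bp insert (the real adapter sequence is proprietary to the protocol;
#: this stand-in carries a BsgI recognition site, GTGCAG, at the documented
#: geometry and is free of AluI sites and of the loop sequence).
SYNTHETIC_C_ARM = "CAGTGCAGAACCGGTATCACT"


def alui_sites(seq: str) -> list[int]:
    """0-based positions of the C in every (possibly overlapping) AGCT.

    The cut position is the index of the C: AluI cuts AG^CT.
    """
    return [m.start() + 2 for m in _ALUI.finditer(seq)]


@dataclass(frozen=True)
class AluIFragment:
    """One AluI restriction fragment, 0-based half-open on its transcript."""

    transcript_id: str
    start: int
    end: int
    left_cut: bool
    right_cut: bool
    seq: str

    def __post_init__(self) -> None:
        if self.left_cut and not self.seq.startswith("CT"):
            raise ValidationError(f"{self.transcript_id}:{self.start}: cut fragment must start CT")
        if self.right_cut and not self.seq.endswith("AG"):
            raise ValidationError(f"{self.transcript_id}:{self.start}: cut fragment must end AG")

    @property
    def fragment_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"


def digest_aluI(transcript: Transcript) -> list[AluIFragment]:
    """Cut between G and C of every AGCT; fragments tile the transcript."""
    cuts = alui_sites(transcript.seq)
    bounds = [0, *cuts, transcript.length]
    frags = []
    for i in range(len(bounds) - 1):
        start, end = bounds[i], bounds[i + 1]
        frags.append(
            AluIFragment(
                transcript_id=transcript.id,
                start=start,
                end=end,
                left_cut=i > 0,
                right_cut=i < len(bounds) - 2,
                seq=transcript.seq[start:end],
            )
        )
    return frags


@dataclass(frozen=True)
class ShRNAVector:
    """A 19–20 nt guide derived from one side of one AluI site."""

    vector_id: str
    transcript_id: str
    gene_label: str
    site_index: int
    side: str  # "left" | "right"
    guide: str
    realizable: bool
    library_of_origin: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be left/right, got {self.side}")
        if self.realizable and len(self.guide) not in (19, 20):
            raise ValidationError(
                f"{self.vector_id}: realizable guide must be 19–20 nt, got {len(self.guide)}"
            )


def enumerate_vectors(transcript: Transcript, config: Config | None = None) -> list[ShRNAVector]:
    """All candidate vectors of a transcript, two per AluI site.

    For site ``i`` (between fragment ``i`` and fragment ``i+1``):

    * the *right* guide is the first ``stem_len`` nt of the downstream
      fragment (top strand, starts CT);
    * the *left* guide is the first ``stem_len`` nt of the reverse
      complement of the upstream fragment (bottom strand, reading away from
      the cut, also starts CT).

    Candidates whose source fragment is shorter than ``stem_len`` are marked
    unrealizable but still returned, so ``len(result)`` is the theoretical
    maximum 2 × (number of AluI sites).
    """
    config = config or Config()
    frags = digest_aluI(transcript)
    n_sites = len(frags) - 1
    out: list[ShRNAVector] = []
    for site in range(n_sites):
        upstream, downstream = frags[site], frags[site + 1]
        for side, source in (("left", reverse_complement(upstream.seq)), ("right", downstream.seq)):
            guide = source[: config.stem_len]
            out.append(
                ShRNAVector(
                    vector_id=f"{transcript.id}:s{site}:{side}",
                    transcript_id=transcript.id,
                    gene_label=transcript.gene_label,
                    site_index=site,
                    side=side,
                    guide=guide,
                    realizable=len(guide) == config.stem_len,
                )
            )
    return out


def max_possible_vectors(transcript_or_seq: Transcript | str) -> int:
    """Theoretical maximum when AluI sites are maximally used: 2 per site."""
    seq = transcript_or_seq if isinstance(transcript_or_seq, str) else transcript_or_seq.seq
    return 2 * len(alui_sites(seq))


@dataclass(frozen=True)
class AdapterGeometry:
    """Lengths governing the enzymatic insert arithmetic.

    BpmI cuts 16 bp away from its adapter-A recognition site, exactly at
    the restored AluI junction, so no adapter-A arm remains in the released
    insert (``arm_len = 0``). The 91-bp identity is then
    ``2·arm_len + 2·stem_len + adapterC_core_len = insert_len_expected``
    with a 51-bp palindromic adapter-C center that contains the 9-nt loop;
    BsgI (cutting 16 bp from its sites inside that center) later trims the
    vector down to the bare stem-loop-stem.
    """

    arm_len: int = 0
    adapterC_core_len: int = 51
    mmeI_capture: tuple[int, int] = (18, 2)  # 18 bp + 2-nt overhang
    bpmI_offset: int = 16
    bsgI_offset: int = 16
    insert_len_expected: int = 91

    def __post_init__(self) -> None:
        for name in ("adapterC_core_len", "bpmI_offset", "bsgI_offset", "insert_len_expected"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.arm_len < 0:
            raise ConfigurationError("arm_len must be non-negative")

    def validate_for(self, stem_len: int) -> None:
        total = 2 * self.arm_len + 2 * stem_len + self.adapterC_core_len
        if total != self.insert_len_expected:
            raise ConfigurationError(
                f"insert geometry inconsistent: 2·{self.arm_len} + 2·{stem_len} + "
                f"{self.adapterC_core_len} = {total} != {self.insert_len_expected}"
            )

    @classmethod
    def default_for(cls, stem_len: int) -> "AdapterGeometry":
        if stem_len == 20:
            return cls()
        if stem_len == 19:
            return cls(adapterC_core_len=53)
        raise ConfigurationError(f"no default geometry for stem_len={stem_len}")


@dataclass(frozen=True)
class InsertRecord:
    """The double-stranded product of the simulated BpmI release."""

    vector_id: str
    seq: str  # top strand
    stem: str
    center: str
    overhang: str  # single-stranded 2-nt extensions on both ends

    @property
    def length(self) -> int:
        return len(self.seq)


def build_insert(
    vector: ShRNAVector,
    geometry: AdapterGeometry | None = None,
    config: Config | None = None,
) -> InsertRecord:
    """Simulate MmeI capture → adapter-C looping → Klenow → BpmI release.

    Returns the expected-length double-stranded insert
    ``[arm][stem][C-core incl. 9-nt loop][revcomp stem][revcomp arm]`` with
    the degenerate 2-nt adapter-C overhang pairing resolved by the Klenow
    fill-in, and AG single-stranded extensions at both released ends (the
    ligation partners of the vector's CT overhangs).
    """
    config = config or Config()
    geometry = geometry or AdapterGeometry.default_for(config.stem_len)
    geometry.validate_for(config.stem_len)
    if not vector.realizable:
        raise ValidationError(f"{vector.vector_id}: cannot build an insert from an unrealizable vector")

    loop = config.loop_seq
    pad = (geometry.adapterC_core_len - len(loop)) // 2
    if 2 * pad + len(loop) != geometry.adapterC_core_len:
        raise ConfigurationError(
            "adapterC_core_len must leave a symmetric double-stranded arm around the loop"
        )
    c_arm = (SYNTHETIC_C_ARM * (pad // len(SYNTHETIC_C_ARM) + 1))[:pad]
    center = c_arm + loop + reverse_complement(c_arm)
    arm = ("ACGACGTCGGTACCTGATCAG" * (geometry.arm_len // 21 + 1))[: geometry.arm_len]
    stem = vector.guide
    seq = arm + stem + center + reverse_complement(stem) + reverse_complement(arm)
    return InsertRecord(vector_id=vector.vector_id, seq=seq, stem=stem, center=center, overhang="AG")


TERMINATOR = "TTTTT"


def assemble_vector_transcript(vector: ShRNAVector, config: Config | None = None) -> str:
    """The hairpin RNA (as DNA) transcribed from the finished vector.

    ``G + guide + loop + revcomp(G + guide)`` followed by the TTTTT
    terminator; the vector G restores part of the AluI site, so the
    transcript begins GCT whenever the guide begins CT.
    """
    config = config or Config()
    if not vector.realizable:
        raise ValidationError(f"{vector.vector_id}: unrealizable vector has no transcript")
    stem = "G" + vector.guide
    return stem + config.loop_seq + reverse_complement(stem) + TERMINATOR


def vectors_to_tsv(vectors: Iterable[ShRNAVector], path: str | Path) -> None:
    rows = [
        {
            "vector_id": v.vector_id,
            "transcript_id": v.transcript_id,
            "gene_label": v.gene_label,
            "site_index": v.site_index,
            "side": v.side,
            "guide": v.guide,
            "realizable": v.realizable,
        }
        for v in vectors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fragments_to_tsv(fragments: Iterable[AluIFragment], path: str | Path) -> None:
    rows = [
        {
            "fragment_id": f.fragment_id,
            "transcript_id": f.transcript_id,
            "start": f.start,
            "end": f.end,
            "left_cut": f.left_cut,
            "right_cut": f.right_cut,
            "length": len(f.seq),
        }
        for f in fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
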