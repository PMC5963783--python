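"""Synthetic pooled-screen generator with planted suppressor transcripts.

Emulates the experiment end to end without any external data: a random
transcriptome whose planted suppressors are expressed in arrested (tester)
cells but repressed in two transformed (driver) genotypes; SSH-shaped
library compositions derived from the kinetic simulator; selection for
anchorage-independent proliferation in which vectors knocking a true
suppressor down past a threshold seed fast-growing colonies; and
error-bearing FASTQ reads of the integrated stem-loop-stem inserts taken
before and after each of two selection rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import Config
from .errors import ValidationError
from .io import FastqRead, Transcript, reverse_complement
from .library import ShRNAVector, alui_sites, digest_aluI, enumerate_vectors
from .ssh import HybridParams, SpeciesPool, run_ssh

BASES = np.array(list("ACGT"))

#: synthetic flank mimicking the H1-promoter end (…CCCC precedes the vector G)
FLANK5 = "TAGGTAACCCC"
#: synthetic flank after the TTTTT terminator
FLANK3 = "GGATCCGTCGA"

LIBRARY_NAMES = ("LEGO-g1", "LEGO-g2")
SAMPLES = ("pre", "post1", "post2")


@dataclass
class ScreenScenario:
    """All knobs of the synthetic screen; seeded runs are bit-reproducible."""

    n_transcripts: int = 200
    n_suppressors: int = 10
    transcript_len_mean: float = 1500.0
    transcript_len_sd: float = 300.0
    transcript_len_min: int = 200
    min_suppressor_alui_sites: int = 5
    repression_fold_range: tuple[float, float] = (2.0, 5.0)
    induction_fold_range: tuple[float, float] = (2.0, 4.0)
    null_fold_range: tuple[float, float] = (0.7, 1.4)
    nonfunctional_fraction: float = 2.0 / 11.0
    knockdown_threshold: float = 0.5
    growth_boost: float = 50.0
    offtarget_rate: float = 0.0
    colonies_sampled: int = 150_000
    reads_per_sample: int = 50_000
    sequencing_error_rate: float = 0.002
    n_rounds: int = 2
    barcodes: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nonfunctional_fraction", "knockdown_threshold", "offtarget_rate",
                     "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.n_suppressors > self.n_transcripts:
            raise ValidationError("planted suppressors must be a subset of the transcriptome")
        if self.growth_boost <= 0:
            raise ValidationError("growth_boost must be positive")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_transcriptome(
    scenario: ScreenScenario,
    rng: np.random.Generator | None = None,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Random ACGT transcripts plus a per-gene expression-fold table.

    Planted suppressors are induced on anchor loss and repressed in both
    transformed genotypes (folds drawn above the 1.66 flag threshold) and
    are resampled until they carry at least ``min_suppressor_alui_sites``
    AluI sites, emulating the multi-site transcripts the enzymatic chemistry
    needs; other transcripts get near-unity fold changes.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.rng_seed)
    lengths = np.maximum(
        scenario.transcript_len_min,
        rng.normal(scenario.transcript_len_mean, scenario.transcript_len_sd, scenario.n_transcripts).astype(int),
    )
    planted = set(rng.choice(scenario.n_transcripts, scenario.n_suppressors, replace=False).tolist())
    transcripts: list[Transcript] = []
    rows = []
    for i in range(scenario.n_transcripts):
        seq = _random_seq(rng, int(lengths[i]))
        if i in planted:
            while len(alui_sites(seq)) < scenario.min_suppressor_alui_sites:
                seq = _random_seq(rng, int(lengths[i]))
        tid, gene = f"T{i:04d}", f"GENE{i:04d}"
        transcripts.append(Transcript(id=tid, gene_label=gene, seq=seq))
        expr = float(rng.lognormal(mean=3.0, sigma=1.0))
        if i in planted:
            g1, g2 = rng.uniform(*scenario.repression_fold_range, size=2)
            ind = rng.uniform(*scenario.induction_fold_range)
        else:
            g1, g2 = rng.uniform(*scenario.null_fold_range, size=2)
            ind = rng.uniform(*scenario.null_fold_range)
        rows.append(
            {
                "transcript_id": tid,
                "gene": gene,
                "expr_tester": expr,
                "repression_fold_genotype1": float(g1),
                "repression_fold_genotype2": float(g2),
                "induction_fold_anchor_loss": float(ind),
                "is_planted": i in planted,
            }
        )
    return transcripts, pd.DataFrame(rows)


def library_composition(
    transcripts: Sequence[Transcript],
    expression: pd.DataFrame,
    genotype_col: str,
    config: Config | None = None,
    params: HybridParams | None = None,
) -> pd.DataFrame:
    """SSH-shaped per-vector composition of one library.

    Tester concentrations follow arrested-cell expression; driver
    concentrations divide by the genotype's repression fold. Every AluI
    fragment inherits its transcript's molar concentration; after SSH each
    realizable vector inherits the subtracted share of its source fragment
    (the fragment whose cut end the guide reads away from).
    """
    config = config or Config()
    params = params or HybridParams(driver_excess=config.driver_excess)
    expr = expression.set_index("transcript_id")
    frag_ids, tester, driver = [], [], []
    frag_lookup = {}
    for t in transcripts:
        e = float(expr.loc[t.id, "expr_tester"])
        d = e / float(expr.loc[t.id, genotype_col])
        for frag in digest_aluI(t):
            frag_ids.append(frag.fragment_id)
            tester.append(e)
            driver.append(d)
            frag_lookup[(t.id, frag.start)] = frag.fragment_id
    shares = run_ssh(SpeciesPool(tuple(frag_ids), np.array(tester), np.array(driver)), params)

    rows = []
    for t in transcripts:
        frags = digest_aluI(t)
        for v in enumerate_vectors(t, config):
            if not v.realizable:
                continue
            # left guide reads into the upstream fragment, right into the downstream
            source = frags[v.site_index] if v.side == "left" else frags[v.site_index + 1]
            rows.append(
                {
                    "vector_id": v.vector_id,
                    "transcript_id": v.transcript_id,
                    "gene_label": v.gene_label,
                    "site_index": v.site_index,
                    "side": v.side,
                    "guide": v.guide,
                    "share": float(shares[source.fragment_id]),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("empty library: no realizable vectors")
    df["share"] = df["share"] / df["share"].sum()
    return df


def assign_efficacies(
    catalog: pd.DataFrame,
    planted_transcripts: set[str],
    scenario: ScreenScenario,
    config: Config,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-vector knockdown efficacy and transforming status (ground truth).

    Efficacy is a property of the guide, drawn once per distinct vector:
    zero with the nonfunctional fraction, otherwise uniform over the
    knockdown range. A vector transforms iff it targets a planted suppressor
    and its efficacy reaches the transformation threshold — plus an optional
    off-target Bernoulli for vectors targeting anything else.
    """
    lo, hi = config.knockdown_range
    out = catalog.drop_duplicates("vector_id").copy()
    n = len(out)
    functional = rng.random(n) >= scenario.nonfunctional_fraction
    eff = np.where(functional, rng.uniform(lo, hi, size=n), 0.0)
    on_target = out["transcript_id"].isin(planted_transcripts).to_numpy()
    transforming = on_target & (eff >= scenario.knockdown_threshold)
    if scenario.offtarget_rate > 0:
        transforming |= (~on_target) & (rng.random(n) < scenario.offtarget_rate)
    out["efficacy"] = eff
    out["is_transforming"] = transforming
    return out.set_index("vector_id")


def simulate_selection(
    composition: pd.DataFrame,
    efficacies: pd.DataFrame,
    scenario: ScreenScenario,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pre/post copy-number table for one library over two selection rounds.

    The pre-selection pool is a multinomial draw of infected cells; each
    round multiplies transforming vectors' weights by the colony-growth
    boost while non-transforming vectors persist at single-cell carryover
    weight, followed by a fresh multinomial draw.
    """
    if composition.empty:
        raise ValidationError("empty library composition")
    share = composition["share"].to_numpy()
    transforming = efficacies.loc[composition["vector_id"], "is_transforming"].to_numpy()
    counts = {"pre": rng.multinomial(scenario.colonies_sampled, share / share.sum())}
    current = counts["pre"].astype(float)
    for r in range(1, scenario.n_rounds + 1):
        weights = current * np.where(transforming, scenario.growth_boost, 1.0)
        total = weights.sum()
        if total <= 0:
            raise ValidationError("selection removed every vector")
        counts[f"post{r}"] = rng.multinomial(scenario.colonies_sampled, weights / total)
        current = counts[f"post{r}"].astype(float)
    out = composition[["vector_id", "guide"]].copy()
    for name, c in counts.items():
        out[name] = c
    return out


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def emit_reads(
    counts: pd.Series,
    guides: pd.Series,
    scenario: ScreenScenario,
    config: Config,
    rng: np.random.Generator,
    sample: str = "sample",
    barcode: str | None = None,
) -> list[FastqRead]:
    """FASTQ reads of one sample, proportional to vector copy numbers.

    Each read covers the integrated hairpin:
    ``flank + G + guide + loop + revcomp(guide) + C + TTTTT + flank`` with
    per-base substitution errors at the configured rate.
    """
    total = int(counts.sum())
    if total <= 0:
        raise ValidationError(f"sample {sample}: no copies to sequence")
    n_reads = rng.multinomial(scenario.reads_per_sample, counts.to_numpy() / total)
    prefix = (barcode or "") + FLANK5
    reads: list[FastqRead] = []
    for (vector_id, n) in zip(counts.index, n_reads):
        if n == 0:
            continue
        guide = guides[vector_id]
        template = (
            prefix + "G" + guide + config.loop_seq + reverse_complement(guide) + "C" + "TTTTT" + FLANK3
        )
        qual = "I" * len(template)
        for i in range(n):
            seq = _apply_errors(template, rng, scenario.sequencing_error_rate)
            reads.append(FastqRead(f"{sample}:{vector_id}:{i}", seq, qual))
    return reads


@dataclass
class ScreenResult:
    """Everything one synthetic screen produced, ready for deconvolution."""

    transcripts: list[Transcript]
    expression: pd.DataFrame
    catalogs: dict[str, pd.DataFrame]  # library -> composition catalog
    efficacies: pd.DataFrame
    count_tables: dict[str, pd.DataFrame]  # library -> vector copy numbers per sample
    reads: dict[tuple[str, str], list[FastqRead]]  # (library, sample) -> reads
    truth: pd.DataFrame  # planted-suppressor ground truth


def run_screen(
    scenario: ScreenScenario | None = None,
    config: Config | None = None,
    params: HybridParams | None = None,
) -> ScreenResult:
    """Generate a complete two-library screen from a single seed."""
    scenario = scenario or ScreenScenario()
    config = config or Config()
    root = np.random.SeedSequence(scenario.rng_seed)
    seeds = root.spawn(2 + 2 * len(LIBRARY_NAMES))
    rng_genome = np.random.default_rng(seeds[0])
    rng_eff = np.random.default_rng(seeds[1])

    transcripts, expression = generate_transcriptome(scenario, rng_genome)
    planted = set(expression.loc[expression["is_planted"], "transcript_id"])

    catalogs, count_tables, reads = {}, {}, {}
    efficacies = None
    genotype_cols = ("repression_fold_genotype1", "repression_fold_genotype2")
    for li, (library, genotype_col) in enumerate(zip(LIBRARY_NAMES, genotype_cols)):
        catalog = library_composition(transcripts, expression, genotype_col, config, params)
        if efficacies is None:
            # efficacy is a property of the vector, shared across libraries
            union = catalog[["vector_id", "transcript_id", "guide"]]
            efficacies = assign_efficacies(union, planted, scenario, config, rng_eff)
        rng_sel = np.random.default_rng(seeds[2 + 2 * li])
        rng_seq = np.random.default_rng(seeds[3 + 2 * li])
        table = simulate_selection(catalog, efficacies, scenario, rng_sel)
        catalogs[library] = catalog
        count_tables[library] = table
        guides = table.set_index("vector_id")["guide"]
        for sample in SAMPLES[: scenario.n_rounds + 1]:
            counts = table.set_index("vector_id")[sample]
            reads[(library, sample)] = emit_reads(
                counts, guides, scenario, config, rng_seq, sample=f"{library}.{sample}"
            )
    truth = expression[expression["is_planted"]][["transcript_id", "gene"]].reset_index(drop=True)
    return ScreenResult(
        transcripts=transcripts,
        expression=expression,
        catalogs=catalogs,
        efficacies=efficacies,
        count_tables=count_tables,
        reads=reads,
        truth=truth,
    )
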