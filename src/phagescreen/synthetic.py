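"""Synthetic phage-selection screens.

This module generates the three library types (transposon insertion pool,
dual-barcoded fragment map, CRISPRi guide library) on a model genome, and
simulates the strong positive selection a lytic phage applies to a pooled
culture: sensitive strains are killed with high probability while resistant
strains keep growing, so a handful of resistant strains absorb most of the
sequencing reads at the end of the assay.

The survival model is deliberately simple — a deterministic expected-
abundance update followed by a single multinomial sequencing draw — so that
closed-form expectations are available for testing.  Under no selection
(``kill_prob_sensitive=0`` and ``doublings_resistant=0``) the expected
start and end abundances are identical, giving an exact null for
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phagescreen.containers import CountTable

NUCLEOTIDES = np.array(list("ACGT"))

#: resistance classes recognized in :attr:`SelectionScenario.resistance_map`
RESISTANCE_CLASSES = {"receptor_knockout", "overexpression_suppressor", "neutral"}


class BarcodeCollisionError(RuntimeError):
    """Could not generate the requested number of unique barcodes."""


@dataclass(frozen=True)
class GenomeModel:
    """Single circular replicon with consecutively numbered genes.

    Gene ``i`` occupies a 1-based inclusive interval; genes are separated by
    a fixed intergenic gap, so the total genome length is
    ``sum(gene_length_bp) + n_genes * intergenic_gap_bp``.
    """

    gene_length_bp: tuple[int, ...]
    intergenic_gap_bp: int = 0
    scaffold: str = "chr"

    def __post_init__(self):
        if any(l <= 0 for l in self.gene_length_bp):
            raise ValueError("gene lengths must be positive")
        if self.intergenic_gap_bp < 0:
            raise ValueError("intergenic gap must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_length_bp)

    @property
    def length(self) -> int:
        return int(sum(self.gene_length_bp)) + self.n_genes * self.intergenic_gap_bp

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]

    def gene_intervals(self) -> pd.DataFrame:
        """1-based inclusive [start, end] per gene, in genome order."""
        lengths = np.asarray(self.gene_length_bp, dtype=np.int64)
        starts = np.empty(self.n_genes, dtype=np.int64)
        pos = 1
        for i, l in enumerate(lengths):
            starts[i] = pos
            pos += l + self.intergenic_gap_bp
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "start": starts, "end": starts + lengths - 1}
        )

    @classmethod
    def regular(cls, n_genes: int, gene_length_bp: int = 1000, intergenic_gap_bp: int = 100):
        """Convenience constructor with equal-length genes."""
        return cls(tuple([gene_length_bp] * n_genes), intergenic_gap_bp)


@dataclass
class SelectionScenario:
    """One phage-selection condition applied to a pooled library.

    ``resistance_map`` assigns genes a resistance class: disrupting (or
    knocking down) a ``receptor_knockout`` gene makes a strain resistant;
    a fragment is resistant iff it fully covers an
    ``overexpression_suppressor`` gene; everything else is sensitive.
    Sensitive strains survive with probability ``1 - kill_prob_sensitive``
    (attenuated on solid plates, a less stringent selection environment),
    while resistant strains additionally double ``doublings_resistant``
    times during the assay.
    """

    phage_name: str
    moi: float
    assay_format: str = "liquid"
    resistance_map: dict[str, str] = field(default_factory=dict)
    kill_prob_sensitive: float = 0.999
    doublings_resistant: float = 4.0
    read_depth: int = 1_000_000
    seed: int = 0
    #: multiplies the kill probability when ``assay_format == "solid"``
    solid_kill_attenuation: float = 0.9
    #: lognormal sigma of the (otherwise uniform) start abundances
    start_abundance_sigma: float = 0.5
    set_label: str = "set1"

    def __post_init__(self):
        if not 0.0 <= self.kill_prob_sensitive <= 1.0:
            raise ValueError("kill_prob_sensitive must be in [0, 1]")
        if self.assay_format not in ("liquid", "solid"):
            raise ValueError(f"unknown assay format {self.assay_format!r}")
        bad = set(self.resistance_map.values()) - RESISTANCE_CLASSES
        if bad:
            raise ValueError(f"unknown resistance class(es): {sorted(bad)}")

    @property
    def effective_kill_prob(self) -> float:
        if self.assay_format == "solid":
            return self.kill_prob_sensitive * self.solid_kill_attenuation
        return self.kill_prob_sensitive


def _random_barcodes(rng: np.random.Generator, n: int, length: int, max_rounds: int = 20):
    """Draw ``n`` distinct random DNA ``length``-mers, retrying collisions."""
    if n == 0:
        return np.array([], dtype=object)
    if 4**length < n:
        raise BarcodeCollisionError(f"alphabet too small for {n} unique {length}-mers")
    seen: dict[str, None] = {}
    need = n
    for _ in range(max_rounds):
        draws = rng.integers(0, 4, size=(need, length))
        for row in draws:
            bc = "".join(NUCLEOTIDES[row])
            if bc not in seen:
                seen[bc] = None
        need = n - len(seen)
        if need <= 0:
            return np.array(list(seen)[:n], dtype=object)
    raise BarcodeCollisionError(f"could not generate {n} unique barcodes after {max_rounds} rounds")


def assign_genes(genome: GenomeModel, positions: np.ndarray):
    """Map 1-based positions to (gene_id | None, fraction within gene)."""
    iv = genome.gene_intervals()
    starts = iv["start"].to_numpy()
    ends = iv["end"].to_numpy()
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx_clipped = np.clip(idx, 0, len(starts) - 1)
    in_gene = (idx >= 0) & (positions <= ends[idx_clipped])
    gene_ids = np.where(in_gene, iv["gene_id"].to_numpy()[idx_clipped], None)
    lengths = (ends - starts + 1)[idx_clipped]
    # midpoint-of-base convention: position p in [start, end] sits at
    # (p - start + 0.5) / length of the ORF
    frac = (positions - starts[idx_clipped] + 0.5) / lengths
    frac = np.where(in_gene, frac, np.nan)
    return gene_ids, frac


def make_barcode_pool(
    genome: GenomeModel, n_strains: int, barcode_len: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Random barcoded transposon insertion pool.

    Insertion positions are uniform over the genome; each strain carries a
    unique barcode and is annotated with the gene it lands in (if any), its
    fractional position within that gene, and whether that fraction lies in
    the central 10–90% of the ORF (the region whose disruptions are scored).
    """
    if n_strains < 0:
        raise ValueError("n_strains must be >= 0")
    rng = np.random.default_rng(seed)
    columns = [
        "barcode", "scaffold", "position", "strand",
        "gene_id", "fraction_within_gene", "central_flag",
    ]
    if n_strains == 0:
        return pd.DataFrame(columns=columns)
    positions = rng.integers(1, genome.length + 1, size=n_strains)
    barcodes = _random_barcodes(rng, n_strains, barcode_len)
    strands = np.where(rng.random(n_strains) < 0.5, "+", "-")
    gene_ids, frac = assign_genes(genome, positions)
    central = np.where(np.isnan(frac), False, (frac >= 0.1) & (frac <= 0.9))
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "scaffold": genome.scaffold,
            "position": positions,
            "strand": strands,
            "gene_id": gene_ids,
            "fraction_within_gene": frac,
            "central_flag": central.astype(bool),
        },
        columns=columns,
    )


def make_fragment_map(
    genome: GenomeModel,
    n_fragments: int,
    mean_len_bp: float = 2500.0,
    sd_len_bp: float = 500.0,
    seed: int = 0,
    min_len_bp: int = 200,
    barcode_len: int = 20,
) -> pd.DataFrame:
    """Random sheared-fragment map for a dual-barcoded expression library.

    Fragment starts are uniform; lengths are normal(mean, sd) truncated
    below at ``min_len_bp``.  Fragments that would wrap the origin are
    redrawn.  ``covered_genes`` lists the genes contained start-to-stop in
    the fragment — partial overlap does not count, matching the attribution
    convention of the downstream gene-score deconvolution.
    """
    if mean_len_bp <= 0:
        raise ValueError("mean_len_bp must be positive")
    rng = np.random.default_rng(seed)
    iv = genome.gene_intervals()
    gstarts = iv["start"].to_numpy()
    gends = iv["end"].to_numpy()
    gids = iv["gene_id"].to_numpy()

    starts = np.empty(n_fragments, dtype=np.int64)
    ends = np.empty(n_fragments, dtype=np.int64)
    filled = 0
    while filled < n_fragments:
        todo = n_fragments - filled
        s = rng.integers(1, genome.length + 1, size=todo)
        l = rng.normal(mean_len_bp, sd_len_bp, size=todo)
        while True:  # truncate below, resampling the short draws
            short = l < min_len_bp
            if not short.any():
                break
            l[short] = rng.normal(mean_len_bp, sd_len_bp, size=int(short.sum()))
        e = s + np.round(l).astype(np.int64) - 1
        keep = e <= genome.length  # no origin wrap
        k = int(keep.sum())
        starts[filled : filled + k] = s[keep]
        ends[filled : filled + k] = e[keep]
        filled += k

    up = _random_barcodes(rng, n_fragments, barcode_len)
    dn = _random_barcodes(rng, n_fragments, barcode_len)
    covered = []
    for s, e in zip(starts, ends):
        i0 = np.searchsorted(gstarts, s, side="left")
        i1 = np.searchsorted(gends, e, side="right")
        covered.append(tuple(gids[i0:i1]))
    return pd.DataFrame(
        {
            "up_barcode": up,
            "dn_barcode": dn,
            "scaffold": genome.scaffold,
            "start": starts,
            "end": ends,
            "covered_genes": covered,
        }
    )


def make_guide_library(
    genome: GenomeModel,
    guides_per_gene: int,
    n_promoters: int = 0,
    n_tfbs: int = 0,
    seed: int = 0,
    guide_len: int = 20,
) -> pd.DataFrame:
    """CRISPRi guide library targeting genes plus optional regulatory features.

    Every targeted feature (gene, promoter, transcription-factor binding
    site) receives ``guides_per_gene`` guides with unique 20-nt spacer
    sequences and a random targeted strand.
    """
    if guides_per_gene < 1:
        raise ValueError("guides_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    targets = (
        [(g, "gene") for g in genome.gene_ids]
        + [(f"p{i + 1:04d}", "promoter") for i in range(n_promoters)]
        + [(f"tf{i + 1:04d}", "tfbs") for i in range(n_tfbs)]
    )
    n_guides = len(targets) * guides_per_gene
    seqs = _random_barcodes(rng, n_guides, guide_len)
    rows = []
    k = 0
    for target_id, feature_class in targets:
        for j in range(guides_per_gene):
            rows.append(
                {
                    "guide_id": f"{target_id}_sg{j + 1}",
                    "sequence": seqs[k],
                    "target_id": target_id,
                    "feature_class": feature_class,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            k += 1
    return pd.DataFrame(rows, columns=["guide_id", "sequence", "target_id", "feature_class", "strand"])


# ---------------------------------------------------------------------------
# selection


def classify_resistant(library: pd.DataFrame, resistance_map: dict[str, str]) -> np.ndarray:
    """Boolean resistance per library member under a resistance map.

    * insertion pool: the strain disrupts a ``receptor_knockout`` gene;
    * fragment map: the fragment fully covers an
      ``overexpression_suppressor`` gene;
    * guide library: the guide targets a ``receptor_knockout`` gene
      (knockdown phenocopies the knockout).
    """
    if "up_barcode" in library.columns:  # fragment map
        suppressors = {g for g, c in resistance_map.items() if c == "overexpression_suppressor"}
        return np.array(
            [bool(suppressors.intersection(genes)) for genes in library["covered_genes"]]
        )
    receptors = {g for g, c in resistance_map.items() if c == "receptor_knockout"}
    if "guide_id" in library.columns:  # guide library
        return (
            (library["feature_class"] == "gene") & library["target_id"].isin(receptors)
        ).to_numpy()
    if "barcode" in library.columns:  # insertion pool
        return library["gene_id"].isin(receptors).to_numpy()
    raise TypeError("unrecognized library table")


def _library_keys(library: pd.DataFrame) -> pd.Index:
    if "up_barcode" in library.columns:
        return pd.Index(library["up_barcode"], name="barcode")
    if "guide_id" in library.columns:
        return pd.Index(library["sequence"], name="guide")
    return pd.Index(library["barcode"], name="barcode")


def simulate_selection(
    library: pd.DataFrame,
    scenario: SelectionScenario,
    n_start_samples: int = 1,
    n_end_samples: int = 1,
) -> CountTable:
    """Simulate one phage-selection assay and return per-sample counts.

    The pooled library starts at near-uniform abundance (lognormal
    dispersion around uniform); start samples are multinomial draws at the
    configured read depth.  End-sample expected abundance is proportional to
    ``start_abundance * survival * 2**doublings`` (``survival = 1`` for
    resistant members, ``1 - kill_prob`` for sensitive ones), again sampled
    multinomially.  All randomness comes from ``scenario.seed``.
    """
    if n_start_samples < 1 or n_end_samples < 1:
        raise ValueError("need at least one start and one end sample")
    keys = _library_keys(library)
    rng = np.random.default_rng(scenario.seed)
    n = len(keys)
    sample_rows = []
    columns: dict[str, np.ndarray] = {}

    if n:
        abundance = rng.lognormal(0.0, scenario.start_abundance_sigma, size=n)
        abundance /= abundance.sum()
        resistant = classify_resistant(library, scenario.resistance_map)
        survival = np.where(resistant, 1.0, 1.0 - scenario.effective_kill_prob)
        growth = np.where(resistant, 2.0**scenario.doublings_resistant, 1.0)
        end_expected = abundance * survival * growth
        total = end_expected.sum()
        if total == 0:
            # every member killed: sequencing sees residual (dead) template,
            # i.e. the start composition
            end_expected = abundance.copy()
        else:
            end_expected = end_expected / total

    for i in range(n_start_samples):
        sid = f"{scenario.set_label}_start_{i + 1}"
        sample_rows.append((sid, scenario.phage_name, scenario.moi, scenario.assay_format,
                            "start", scenario.set_label, i + 1))
        columns[sid] = rng.multinomial(scenario.read_depth, abundance) if n else np.array([], dtype=np.int64)
    for i in range(n_end_samples):
        sid = f"{scenario.set_label}_end_{i + 1}"
        sample_rows.append((sid, scenario.phage_name, scenario.moi, scenario.assay_format,
                            "end", scenario.set_label, i + 1))
        columns[sid] = rng.multinomial(scenario.read_depth, end_expected) if n else np.array([], dtype=np.int64)

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "phage", "moi", "format", "role", "set_label", "replicate"],
    ).set_index("sample_id")
    counts = pd.DataFrame(columns, index=keys)
    return CountTable(counts, samples)


def emit_reads(
    counts: CountTable,
    flank_before: str,
    flank_after: str,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Expand a count table into raw reads, one list per sample.

    Each read is ``flank_before + barcode + flank_after`` with independent
    per-base substitution errors at ``error_rate``.  The read multiset of a
    sample reproduces that sample's counts exactly (before errors).
    """
    if not flank_before or not flank_after:
        raise ValueError("flanks must be nonempty")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for sid in counts.counts.columns:
        col = counts.counts[sid]
        reads: list[str] = []
        for barcode, k in col.items():
            reads.extend([flank_before + str(barcode) + flank_after] * int(k))
        if error_rate > 0 and reads:
            mutated = []
            for read in reads:
                arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
                for p in hits:
                    choices = [b for b in b"ACGT" if b != arr[p]]
                    arr[p] = choices[rng.integers(0, 3)]
                mutated.append(arr.tobytes().decode())
            reads = mutated
        out[sid] = reads
    return out
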