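"""Seeded generators for every pipeline stage, with ground truth attached.

Each generator is a pure function of its arguments and seed: the same call
produces bit-identical data, and every dataset ships a machine-readable
``truth`` record sufficient to score downstream estimates.

Statistical structure emulated:

* gel-shift titrations — Hill-equation fraction bound plus additive Gaussian
  noise, clipped to [0, 1], on a log-spaced concentration grid;
* ITC thermograms — one-set-of-sites per-injection heats plus proportional
  and additive Gaussian noise, with an optional constant-dilution blank;
* bright-field droplet images — Gaussian background with darker rasterized
  ellipses, 12-bit by default, plus the exact truth mask;
* CLIP read sets — a toy genome of 8 contiguous category blocks, reads drawn
  multinomially with planted per-category fold enrichments, anticodon-loop-
  biased cross-link positions inside tRNA genes, and configurable rates of
  injected PCR duplicates / short reads / low-score reads for filter tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .binding import TitrationCurve, hill_fraction
from .clip import CATEGORIES as CATEGORY_ORDER
from .clip import AlignedRead, GenomeAnnotation, TRNAModel
from .dropletquant import BrightFieldImage
from .itc import ITCParams, ITCProtocol, Thermogram, predicted_heats

DEFAULT_X_GRID_NM = tuple(np.geomspace(20.0, 2000.0, 12))

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# gel-shift titrations


def gen_binding_curve(
    kd_nM: float = 460.0,
    n: float = 2.8,
    x_grid_nM=DEFAULT_X_GRID_NM,
    noise_sd: float = 0.03,
    seed=None,
) -> tuple[TitrationCurve, dict]:
    """One simulated direct-titration curve (trace RNA, 12 log-spaced
    protein concentrations from 20 nM to 2 uM by default)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    x = np.asarray(x_grid_nM, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration grid must be strictly positive")
    rng = _rng(seed)
    y_true = hill_fraction(x, kd_nM, n)
    y = np.clip(y_true + rng.normal(0.0, noise_sd, size=x.size), 0.0, 1.0)
    truth = dict(kd_nM=kd_nM, n=n, noise_sd=noise_sd, y_true=y_true)
    return TitrationCurve(conc_nM=x, fraction_bound=y), truth


# --------------------------------------------------------------------------
# ITC thermograms


def gen_itc_thermogram(
    params: ITCParams,
    protocol: ITCProtocol | None = None,
    proportional_noise: float = 0.02,
    additive_noise_ucal: float = 0.1,
    seed=None,
    blank: bool = False,
    blank_heat_ucal: float = -0.2,
) -> tuple[Thermogram, dict]:
    """One simulated thermogram under the given protocol.

    Noise: per-injection Gaussian with sd = proportional_noise * |heat| +
    additive_noise_ucal.  With ``blank=True`` a constant titrant-into-buffer
    dilution heat is added to the sample channel and shipped as the blank, so
    blank subtraction recovers the noisy binding signal.
    """
    if proportional_noise < 0 or additive_noise_ucal < 0:
        raise ValueError("noise scales must be non-negative")
    if protocol is None:
        protocol = ITCProtocol()
    rng = _rng(seed)
    clean = predicted_heats(protocol, params)
    sd = proportional_noise * np.abs(clean) + additive_noise_ucal
    heats = clean + rng.normal(0.0, 1.0, size=clean.size) * sd
    blank_channel = None
    if blank:
        blank_channel = np.full(clean.size, blank_heat_ucal)
        heats = heats + blank_channel
    truth = dict(
        kd_nM=params.kd_nM, dH_kcal_mol=params.dH_kcal_mol, n=params.n,
        clean_heats=clean,
    )
    return Thermogram(heats_ucal=heats, blank_ucal=blank_channel), truth


# --------------------------------------------------------------------------
# bright-field droplet images


def rasterize_ellipse(shape, center, semi_axes, angle_rad: float = 0.0):
    """Boolean mask of pixels whose centers satisfy the ellipse inequality."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def gen_droplet_image(
    width: int = 500,
    height: int = 500,
    pixel_size_um: float = 0.25,
    ellipses=(),
    background_mean: float = 2000.0,
    background_sd: float = 0.0,
    depth: float = 600.0,
    bit_depth: int = 12,
    seed=None,
    condition: str | None = None,
    replicate: int | None = None,
) -> tuple[BrightFieldImage, dict]:
    """A synthetic bright-field frame with darker elliptical droplets.

    ``ellipses`` is a list of (center_rc, semi_axes_px, angle_rad) tuples.
    Truth carries the exact per-object pixel masks, eccentricities and
    equivalent diameters, the combined mask, and the ground-truth coverage.
    """
    if depth <= 0:
        raise ValueError("droplets must be darker than background (depth > 0)")
    rng = _rng(seed)
    shape = (height, width)
    field = rng.normal(background_mean, background_sd, size=shape) \
        if background_sd > 0 else np.full(shape, float(background_mean))
    combined = np.zeros(shape, dtype=bool)
    objects = []
    for center, semi_axes, angle in ellipses:
        mask = rasterize_ellipse(shape, center, semi_axes, angle)
        combined |= mask
        a, b = max(semi_axes), min(semi_axes)
        count = int(mask.sum())
        objects.append(
            dict(
                center=tuple(center), semi_axes=tuple(semi_axes), angle=angle,
                pixel_count=count,
                eccentricity=float(np.sqrt(1.0 - (b / a) ** 2)),
                equivalent_diameter_um=2.0 * np.sqrt(
                    count * pixel_size_um ** 2 / np.pi
                ),
                clipped=bool(
                    mask[0].any() or mask[-1].any()
                    or mask[:, 0].any() or mask[:, -1].any()
                ),
            )
        )
    field = field - depth * combined
    max_value = 2 ** bit_depth - 1
    if field.min() < 0:
        import warnings

        warnings.warn("intensities clipped at 0", UserWarning, stacklevel=2)
    pixels = np.clip(np.rint(field), 0, max_value).astype(np.uint16)
    truth = dict(
        mask=combined,
        objects=objects,
        coverage_pct=100.0 * combined.sum() / combined.size,
        background_mean=background_mean, background_sd=background_sd,
        depth=depth,
    )
    image = BrightFieldImage(
        pixels=pixels, pixel_size_um=pixel_size_um, bit_depth=bit_depth,
        condition=condition, replicate=replicate,
    )
    return image, truth


# --------------------------------------------------------------------------
# CLIP read sets

DEFAULT_CATEGORY_LENGTHS = {
    "exon": 20000, "intron": 35000, "lincRNA": 8000, "snRNA": 2000,
    "rRNA": 5000, "miRNA": 1000, "tRNA": 1000, "intergenic": 28000,
}

# Canonical 76-nt cloverleaf layout (0-based, contiguous element blocks).
_TRNA_ELEMENT_SPANS = (
    ("acceptor_stem", 0, 8),
    ("d_loop", 8, 22),
    ("anticodon_stem", 22, 32),
    ("anticodon_loop", 32, 39),
    ("variable_loop", 39, 48),
    ("t_loop", 48, 65),
    ("acceptor_stem", 65, 76),
)
TRNA_LENGTH = 76
ANTICODON_START = 34  # 0-based; anticodon occupies 34-36

DEFAULT_CROSSLINK_BIAS = {
    "anticodon_loop": 0.70, "t_loop": 0.15, "d_loop": 0.10, "elsewhere": 0.05
}


def _trna_labels() -> tuple[str, ...]:
    labels = [""] * TRNA_LENGTH
    for name, start, end in _TRNA_ELEMENT_SPANS:
        for i in range(start, end):
            labels[i] = name
    return tuple(labels)


def make_trna_models(
    block_start: int, n_genes: int, chrom: str = "chrT", gap: int = 1,
    seed=None,
) -> list[TRNAModel]:
    """Lay out ``n_genes`` canonical 76-nt tRNA genes with 1-nt spacers."""
    rng = _rng(seed)
    labels = _trna_labels()
    models = []
    pos = block_start
    for g in range(n_genes):
        seq = "".join(rng.choice(_BASES, size=TRNA_LENGTH))
        models.append(
            TRNAModel(
                gene_id=f"tRNA-{g + 1}", chrom=chrom, start=pos,
                end=pos + TRNA_LENGTH, strand="+", sequence=seq,
                element_labels=labels,
                anticodon=(ANTICODON_START, ANTICODON_START + 1,
                           ANTICODON_START + 2),
            )
        )
        pos += TRNA_LENGTH + gap
    return models


def fold_vector(
    category_lengths: dict[str, int], planted: dict[str, float]
) -> dict[str, float]:
    """Complete a per-category fold-enrichment vector so the genome-fraction-
    weighted folds sum to 1 (a proper probability model): the categories in
    ``planted`` keep their folds, the remainder share the residual read mass
    proportionally to genomic extent."""
    total = sum(category_lengths.values())
    fracs = {c: length / total for c, length in category_lengths.items()}
    planted_mass = sum(fracs[c] * f for c, f in planted.items())
    if planted_mass >= 1.0:
        raise ValueError("planted folds absorb more than the whole read mass")
    rest_frac = sum(f for c, f in fracs.items() if c not in planted)
    rest_fold = (1.0 - planted_mass) / rest_frac
    return {
        c: planted.get(c, rest_fold) for c in category_lengths
    }


def gen_clip_dataset(
    category_lengths: dict[str, int] | None = None,
    enrichment: dict[str, float] | None = None,
    n_reads: int = 10000,
    n_trna_genes: int = 13,
    crosslink_bias: dict[str, float] | None = None,
    duplicate_rate: float = 0.0,
    short_read_rate: float = 0.0,
    low_score_rate: float = 0.0,
    seed=None,
) -> tuple[list[AlignedRead], GenomeAnnotation, list[TRNAModel], dict]:
    """A toy genome, a read set with planted enrichments, and its truth.

    The 8 categories are laid out contiguously on one chromosome; the tRNA
    block is subdivided into canonical 76-nt genes (spacer gaps become
    intergenic).  ``enrichment`` maps category -> fold; folds are normalized
    into category probabilities (see :func:`fold_vector` for building vectors
    whose planted folds are exact).  Within tRNA genes, cross-link positions
    are drawn per structural-element bias and the read is placed so its
    truncation site is the drawn position.  ``duplicate_rate`` appends PCR
    copies of sampled reads; ``short_read_rate`` / ``low_score_rate`` inject
    sub-threshold reads.  Truth records the realized per-category fold and
    probabilities, injected-duplicate names, and per-site element labels.
    """
    rng = _rng(seed)
    lengths = dict(category_lengths or DEFAULT_CATEGORY_LENGTHS)
    if any(v <= 0 for v in lengths.values()):
        raise ValueError("category lengths must be positive")
    bias = dict(crosslink_bias or DEFAULT_CROSSLINK_BIAS)

    # contiguous layout on one chromosome; intergenic block last
    chrom = "chrT"
    order = [c for c in lengths if c != "intergenic"] + ["intergenic"]
    offsets, pos = {}, 0
    for cat in order:
        offsets[cat] = pos
        pos += lengths[cat]
    genome_length = pos

    trna_models = make_trna_models(
        offsets["tRNA"], n_trna_genes, chrom=chrom, seed=rng
    )
    if trna_models[-1].end > offsets["tRNA"] + lengths["tRNA"]:
        raise ValueError("tRNA block too small for the requested gene count")
    intervals = {
        cat: [(chrom, offsets[cat], offsets[cat] + lengths[cat])]
        for cat in lengths if cat not in ("intergenic", "tRNA")
    }
    intervals["tRNA"] = [(chrom, m.start, m.end) for m in trna_models]
    annotation = GenomeAnnotation(
        intervals=intervals, chrom_lengths={chrom: genome_length}
    )

    # category probabilities proportional to genomic extent x fold
    eff_lengths = annotation.category_lengths()
    folds = dict.fromkeys(eff_lengths, 1.0)
    folds.update(enrichment or {})
    weights = np.array(
        [eff_lengths[c] * folds[c] for c in CATEGORY_ORDER], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("zero total read probability")
    probs = weights / weights.sum()
    genome_fracs = np.array(
        [eff_lengths[c] / genome_length for c in CATEGORY_ORDER]
    )
    realized_folds = dict(
        zip(CATEGORY_ORDER, np.divide(probs, genome_fracs))
    )

    element_positions: dict[str, np.ndarray] = {}
    labels = _trna_labels()
    for name in set(labels):
        element_positions[name] = np.flatnonzero(
            np.array(labels) == name
        )
    element_names = sorted(element_positions)
    element_weights = np.array(
        [bias.get(name, bias.get("elsewhere", 0.0)) for name in element_names],
        dtype=float,
    )
    # split the catch-all mass between elements that share it
    shared = [i for i, name in enumerate(element_names) if name not in bias]
    if shared and "elsewhere" in bias:
        sizes = np.array([element_positions[element_names[i]].size for i in shared])
        element_weights[shared] = bias["elsewhere"] * sizes / sizes.sum()
    element_weights = element_weights / element_weights.sum()

    reads: list[AlignedRead] = []
    site_elements: list[str] = []
    cat_draws = rng.choice(len(CATEGORY_ORDER), size=n_reads, p=probs)
    for i, ci in enumerate(cat_draws):
        cat = CATEGORY_ORDER[ci]
        barcode = "".join(rng.choice(_BASES, size=9))
        length = int(rng.integers(20, 36))
        score = int(rng.integers(20, 43))
        if cat == "tRNA":
            model = trna_models[int(rng.integers(len(trna_models)))]
            element = element_names[
                int(rng.choice(len(element_names), p=element_weights))
            ]
            p = int(rng.choice(element_positions[element]))
            site = model.start + p  # '+' strand genes
            start = site + 1
            end = min(start + length, genome_length)
            site_elements.append(labels[p])
        else:
            lo, hi = offsets[cat], offsets[cat] + lengths[cat]
            start = int(rng.integers(lo + 1, max(lo + 2, hi - length)))
            end = min(start + length, genome_length)
        reads.append(
            AlignedRead(
                chrom=chrom, start=start, end=end, strand="+",
                score=score, random_barcode=barcode, name=f"read{i}",
                sample_barcode="SAMPLE1",
            )
        )

    truth_category = {
        f"read{i}": CATEGORY_ORDER[ci] for i, ci in enumerate(cat_draws)
    }

    injected_duplicates: list[str] = []
    if duplicate_rate > 0 and reads:
        n_dup = int(round(duplicate_rate * len(reads)))
        for j, src in enumerate(rng.choice(len(reads), size=n_dup)):
            orig = reads[int(src)]
            dup = replace(orig, name=f"dup{j}")
            reads.append(dup)
            injected_duplicates.append(dup.name)

    injected_short: list[str] = []
    if short_read_rate > 0:
        n_short = int(round(short_read_rate * n_reads))
        for j in range(n_short):
            start = int(rng.integers(0, genome_length - 17))
            read = AlignedRead(
                chrom=chrom, start=start, end=start + int(rng.integers(10, 18)),
                strand="+", score=30,
                random_barcode="".join(rng.choice(_BASES, size=9)),
                name=f"short{j}", sample_barcode="SAMPLE1",
            )
            reads.append(read)
            injected_short.append(read.name)

    injected_low_score: list[str] = []
    if low_score_rate > 0:
        n_low = int(round(low_score_rate * n_reads))
        for j in range(n_low):
            start = int(rng.integers(0, genome_length - 30))
            read = AlignedRead(
                chrom=chrom, start=start, end=start + 25, strand="+",
                score=int(rng.integers(0, 10)),
                random_barcode="".join(rng.choice(_BASES, size=9)),
                name=f"lowscore{j}", sample_barcode="SAMPLE1",
            )
            reads.append(read)
            injected_low_score.append(read.name)

    truth = dict(
        folds=realized_folds,
        probabilities=dict(zip(CATEGORY_ORDER, probs)),
        category_lengths=eff_lengths,
        read_category=truth_category,
        site_elements=site_elements,
        crosslink_bias=dict(zip(element_names, element_weights)),
        injected_duplicates=injected_duplicates,
        injected_short=injected_short,
        injected_low_score=injected_low_score,
    )
    return reads, annotation, trna_models, truth
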