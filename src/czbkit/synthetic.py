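"""Labeled synthetic inputs for every pipeline stage.

Generators are deterministic given a seed and always return ground-truth
labels next to the data, so detection, classification, fitting and image
quantification can all be verified offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor

from . import biochem
from .architecture import ArchitectureCall, SUBGROUPS
from .detect import AA20, scan_motif
from .iolib import DomainAnnotation, DoseResponseDataset, ProteinRecord

CZB_LENGTH = 128
CZB_CYS = 52  # 1-based position of the conserved Cys inside the cassette
CZB_HIS = (22, 79, 83)

DECOY_CLASSES = ("decoy_motif_only", "decoy_core_only", "decoy_truncated")

DEFAULT_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Bacteroidetes",
    "Spirochaetes",
    "Candidatus Omnitrophica",
    "Candidatus Woesearchaeota",
)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_per_class: int = 20
    noise_sd: float = 0.05
    architecture_mix: dict = field(
        default_factory=lambda: {sg: 1.0 / len(SUBGROUPS) for sg in SUBGROUPS}
    )
    motif_mutation_rate: float = 0.3
    periplasmic_fraction: float = 0.5  # of membrane chemoreceptors

    def __post_init__(self) -> None:
        total = sum(self.architecture_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("architecture_mix fractions must sum to 1")
        unknown = set(self.architecture_mix) - set(SUBGROUPS)
        if unknown:
            raise ValueError(f"unknown subgroups in mix: {sorted(unknown)}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Sequence cassettes
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def czb_cassette(rng: np.random.Generator) -> str:
    """A ~128-residue domain with the 3His/1Cys core and the alpha-3 motif."""
    seq = list(_random_seq(rng, CZB_LENGTH))
    for h in CZB_HIS:
        seq[h - 1] = "H"
    c = CZB_CYS - 1
    seq[c:c + 7] = [
        "C",
        rng.choice(list("RAKQSTNE")),  # solvent-permissive position 2
        rng.choice(["L", "F"]),
        "G",
        rng.choice(list("AVSTILMN")),
        "W",
        rng.choice(["Y", "L"]),
    ]
    return "".join(seq)


def _ggdef_cassette(rng: np.random.Generator, length: int = 168) -> str:
    seq = list(_random_seq(rng, length))
    mid = length // 2
    seq[mid:mid + 5] = list("GGDEF")
    return "".join(seq)


def _eal_cassette(rng: np.random.Generator, length: int = 150) -> str:
    seq = list(_random_seq(rng, length))
    seq[10:13] = list("EAL")
    return "".join(seq)


def _tm_cassette(rng: np.random.Generator, length: int = 25) -> str:
    return "".join(rng.choice(list("LIVF"), size=length))


def _strip_motifs(seq: str, keep_cys: int | None = None) -> str:
    """Mutate accidental motif matches away (optionally keep one anchor Cys)."""
    out = list(seq)
    changed = True
    while changed:
        changed = False
        for hit in scan_motif(ProteinRecord("probe", "".join(out))):
            if keep_cys is not None and hit.cys_position == keep_cys:
                continue
            out[hit.cys_position + 2] = "A"  # break the Gly position
            changed = True
    return "".join(out)


_ARCH_LAYOUT = {
    # subgroup -> ordered cassette plan; "CZB" is inserted where listed
    "soluble_chemoreceptor": ("MCP", "CZB"),
    "membrane_chemoreceptor": ("TM", "MCP", "CZB"),
    "dgc": ("CZB", "GGDEF"),
    "dgc_eal": ("CZB", "GGDEF", "EAL"),
    "eal_czb": ("CZB", "EAL"),
    "chew_czb": ("CZB", "CheW"),
    "czb_only": ("CZB",),
}


def _compose(
    rng: np.random.Generator, protein_id: str, subgroup: str, periplasmic: bool
) -> tuple[ProteinRecord, list[DomainAnnotation], dict]:
    parts: list[tuple[str, str]] = []  # (domain_name or "", seq)

    def linker(n: int) -> tuple[str, str]:
        return "", _strip_motifs(_random_seq(rng, n))

    if periplasmic:
        layout = ("TM", "CZB", "TM", "MCP")
    else:
        layout = _ARCH_LAYOUT[subgroup]
    for i, name in enumerate(layout):
        if i > 0:
            parts.append(linker(int(rng.integers(8, 16))))
        if name == "CZB":
            parts.append(("CZB", czb_cassette(rng)))
        elif name == "MCP":
            parts.append(("MCP", _strip_motifs(_random_seq(rng, 200))))
        elif name == "GGDEF":
            parts.append(("GGDEF", _strip_motifs(_ggdef_cassette(rng))))
        elif name == "EAL":
            parts.append(("EAL", _strip_motifs(_eal_cassette(rng))))
        elif name == "CheW":
            parts.append(("CheW", _strip_motifs(_random_seq(rng, 140))))
        elif name == "TM":
            parts.append(("TM", _tm_cassette(rng)))

    seq = ""
    annotations: list[DomainAnnotation] = []
    czb_start = czb_cys = None
    for name, s in parts:
        start = len(seq) + 1
        seq += s
        if name:
            annotations.append(DomainAnnotation(protein_id, name, start, len(seq)))
        if name == "CZB":
            czb_start = start
            czb_cys = start + CZB_CYS - 1
    record = ProteinRecord(protein_id, seq)
    truth = dict(
        protein_id=protein_id,
        label=subgroup,
        accepted=True,
        periplasmic=periplasmic,
        czb_start=czb_start,
        czb_cys=czb_cys,
    )
    return record, annotations, truth


def _decoy(
    rng: np.random.Generator, protein_id: str, decoy_class: str
) -> tuple[ProteinRecord, dict]:
    cassette = czb_cassette(rng)
    if decoy_class == "decoy_motif_only":
        # strip the His core within the window of the Cys
        seq = list(cassette)
        window = range(max(0, CZB_CYS - 1 - 45), min(len(seq), CZB_CYS + 45))
        his = [i for i in window if seq[i] == "H"]
        for i in his[: max(0, len(his) - 2)]:
            seq[i] = "Q"
        # keep at most 2 His in the window
        remaining = [i for i in window if seq[i] == "H"]
        for i in remaining[2:]:
            seq[i] = "Q"
        seq = "".join(seq)
    elif decoy_class == "decoy_core_only":
        seq = _strip_motifs(cassette)  # breaks every motif incl. the real one
    elif decoy_class == "decoy_truncated":
        seq = cassette[:90]  # region [1, 90] fails the 100-residue coverage
    else:
        raise ValueError(f"unknown decoy class {decoy_class!r}")
    record = ProteinRecord(protein_id, seq)
    truth = dict(
        protein_id=protein_id, label=decoy_class, accepted=False,
        periplasmic=False, czb_start=None, czb_cys=None,
    )
    return record, truth


def gen_czb_proteins(
    config: GeneratorConfig,
    n_proteins: int = 200,
    n_decoys: int = 0,
) -> tuple[list[ProteinRecord], list[DomainAnnotation], pd.DataFrame]:
    """Positives composed per the architecture mix, plus near-miss decoys.

    Returns (records, domain annotations, truth table).  Decoys cycle
    through the three near-miss classes, each targeting exactly one of the
    four identification attributes.
    """
    rng = config.rng()
    mix = config.architecture_mix
    counts = _allocate(n_proteins, [mix.get(sg, 0.0) for sg in SUBGROUPS])
    records: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    truth_rows: list[dict] = []
    idx = 0
    for sg, count in zip(SUBGROUPS, counts):
        for _ in range(count):
            idx += 1
            peri = (
                sg == "membrane_chemoreceptor"
                and rng.random() < config.periplasmic_fraction
            )
            rec, anns, truth = _compose(rng, f"SYN{idx:05d}", sg, peri)
            records.append(rec)
            annotations.extend(anns)
            truth_rows.append(truth)
    for d in range(n_decoys):
        idx += 1
        rec, truth = _decoy(rng, f"SYN{idx:05d}", DECOY_CLASSES[d % len(DECOY_CLASSES)])
        records.append(rec)
        truth_rows.append(truth)
    truth = pd.DataFrame(truth_rows)
    truth["seed"] = config.seed
    return records, annotations, truth


def czb_seed_rows(
    records: list[ProteinRecord], truth: pd.DataFrame
) -> list[str]:
    """Extract the true CZB cassettes of accepted proteins (profile seeds)."""
    by_id = {r.id: r for r in records}
    rows = []
    for t in truth.itertuples(index=False):
        if t.accepted and t.czb_start is not None and not pd.isna(t.czb_start):
            start = int(t.czb_start)
            rows.append(by_id[t.protein_id].sequence[start - 1:start - 1 + CZB_LENGTH])
    return rows


def _allocate(total: int, fractions: list[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` across fractions."""
    raw = [f * total for f in fractions]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

def gen_dose_response(
    model: str,
    params: dict,
    doses,
    reps: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    label: str = "",
) -> DoseResponseDataset:
    """Simulate a titration with multiplicative Gaussian noise.

    ``model`` is one of hill / twostate / linear; truth parameters are
    embedded in the dataset metadata.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    if model == "hill":
        clean = biochem.hill_response(
            doses, params["K_half"], params.get("n", 2.0), params.get("A", 1.0)
        )
    elif model == "twostate":
        clean = biochem.tight_binding_y(
            doses, params["K_D"], params["y_min"], params["y_max"]
        )
    elif model == "linear":
        clean = params["intercept"] + params["slope"] * doses
    else:
        raise ValueError(f"unknown model {model!r}")
    clean = np.asarray(clean, dtype=float)
    noise = rng.normal(0.0, noise_sd, size=(len(doses), reps)) if noise_sd > 0 else 0.0
    resp = np.maximum(clean[:, None] * (1.0 + noise), 0.0)
    if np.isscalar(noise):
        resp = np.repeat(clean[:, None], reps, axis=1)
    meta = {"model": model, "seed": str(seed)}
    meta.update({f"truth_{k}": repr(v) for k, v in params.items()})
    return DoseResponseDataset(doses, resp, label=label or model, meta=meta)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

RED_HSB = (8.0, 0.90, 0.80)  # hue on the 0-255 scale
BROWN_HSB = (45.0, 0.85, 0.55)


def _hsb_to_rgb8(h255: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    hsv = np.stack([h255 / 255.0, s, v], axis=-1)
    rgb = skcolor.hsv2rgb(hsv)
    return (rgb * 255.0).round().astype(np.uint8)


def gen_colony_image(
    red_fraction: float,
    size: tuple[int, int] = (120, 120),
    seed: int = 0,
    hue_jitter: float = 2.0,
    border: int = 10,
) -> tuple[np.ndarray, dict]:
    """An RGB colony image with a known red/(red+brown) pixel fraction.

    A black border frames a colony of red- and brown-hued pixels arranged
    randomly; the truth dict carries the exact generated fraction.
    """
    if not 0.0 <= red_fraction <= 1.0:
        raise ValueError("red_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = size
    inner_h, inner_w = h - 2 * border, w - 2 * border
    if inner_h <= 0 or inner_w <= 0:
        raise ValueError("border too large for image size")
    n_colony = inner_h * inner_w
    n_red = int(round(red_fraction * n_colony))
    flags = np.zeros(n_colony, dtype=bool)
    flags[:n_red] = True
    rng.shuffle(flags)

    hue = np.where(flags, RED_HSB[0], BROWN_HSB[0]).astype(float)
    hue += rng.uniform(-hue_jitter, hue_jitter, size=n_colony)
    sat = np.where(flags, RED_HSB[1], BROWN_HSB[1])
    val = np.where(flags, RED_HSB[2], BROWN_HSB[2])
    colony = _hsb_to_rgb8(hue, sat, val).reshape(inner_h, inner_w, 3)

    image = np.zeros((h, w, 3), dtype=np.uint8)
    image[border:h - border, border:w - border] = colony
    truth = dict(
        red_fraction=n_red / n_colony,
        red_pixels=n_red,
        brown_pixels=n_colony - n_red,
        background_pixels=h * w - n_colony,
        seed=seed,
    )
    return image, truth


def gen_tube_image(
    pellicle_intensity: float,
    band_rows: tuple[int, int],
    size: tuple[int, int] = (3000, 60),
    background: float = 230.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A grayscale-RGB tube image with a dark stain band of known depth.

    Rows ``band_rows`` (inclusive) are darkened by ``pellicle_intensity``
    below the light background.  Returns (image, truth per-row profile).
    """
    h, w = size
    lo, hi = band_rows
    if lo < 0 or hi >= h or lo > hi:
        raise ValueError("band outside image")
    if not 0.0 <= pellicle_intensity <= background:
        raise ValueError("pellicle_intensity must be in [0, background]")
    profile = np.full(h, background, dtype=float)
    profile[lo:hi + 1] = background - pellicle_intensity
    image = np.repeat(
        np.repeat(profile[:, None], w, axis=1)[:, :, None], 3, axis=2
    ).round().astype(np.uint8)
    truth = np.round(profile)
    return image, truth


# ---------------------------------------------------------------------------
# Species tables
# ---------------------------------------------------------------------------

_CATEGORY_SUBGROUPS = {
    "chemoreceptor_only": ("soluble_chemoreceptor",),
    "dgc_only": ("dgc",),
    "both": ("soluble_chemoreceptor", "dgc"),
    "neither": ("czb_only",),
}


def gen_species_table(
    mix: dict,
    n_species: int = 100,
    phyla=DEFAULT_PHYLA,
    seed: int = 0,
) -> tuple[list[ArchitectureCall], pd.DataFrame, pd.DataFrame]:
    """Species with architecture calls matching the requested category mix.

    ``mix`` maps category name -> fraction (fractions sum to 1; counts are
    allocated exactly by largest remainder).  Returns (architecture calls,
    taxonomy table, truth table).
    """
    from .cooccurrence import CATEGORIES

    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = _allocate(n_species, [mix.get(c, 0.0) for c in CATEGORIES])
    calls: list[ArchitectureCall] = []
    tax_rows: list[dict] = []
    truth_rows: list[dict] = []
    pid = 0
    sp = 0
    for category, count in zip(CATEGORIES, counts):
        for _ in range(count):
            sp += 1
            species = f"Genus{sp:04d} species{sp:04d}"
            phylum = phyla[int(rng.integers(0, len(phyla)))]
            candidate = phylum.startswith("Candidatus")
            for sg in _CATEGORY_SUBGROUPS[category]:
                pid += 1
                protein_id = f"TAX{pid:05d}"
                calls.append(ArchitectureCall(protein_id, sg, "N", False, 300))
                tax_rows.append(
                    dict(
                        protein_id=protein_id,
                        species=species,
                        genus=species.split()[0],
                        phylum=phylum,
                        candidate_phylum_flag=candidate,
                    )
                )
            truth_rows.append(
                dict(species=species, category=category, phylum=phylum,
                     candidate_phylum=candidate)
            )
    order = rng.permutation(len(calls))
    calls = [calls[i] for i in order]
    taxonomy = pd.DataFrame([tax_rows[i] for i in order])
    return calls, taxonomy, pd.DataFrame(truth_rows)
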