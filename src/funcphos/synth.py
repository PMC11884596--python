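"""Synthetic proteins with planted functional phosphorylation sites.

The generator emulates the statistical structure the predictor assumes,
without any pretence of physical realism: backbones alternate ideal
α-helix segments with self-avoiding random-coil segments (3.8 Å Cα steps);
helix residues get high model confidence (pLDDT 70–95), coil residues low
(30–60); sequences are composition-biased per segment type; and sidechain
pseudo-atoms sit one ångström off the Cα in a random direction.

Packing is sequence-coupled, as it is in real proteins: each segment
carries an "anchored" flag drawn independently of its helix/coil kind.
Anchored segments are placed against the growing protein core and draw
extra hydrophobic/aromatic letters (W/F/M); unanchored segments drift
outward.  Network centrality is therefore high around anchored segments
and low elsewhere — a genuinely structural feature (computed from the 3D
contact graph) that a sequence model can nevertheless largely infer from
local composition, mirroring how language-model embeddings capture
structural context from sequence alone.

Candidate sites are S/T/Y residues planted along the chain.  Their labels
follow a known logistic rule over three structural/sequence features —
coil membership, z-scored eigenvector centrality in the whole-protein
contact graph, and a ±3 sequence motif (R at −3, P at +1) — so positives
are coil-enriched and centrality-enriched by construction, mirroring what
is observed on real functional-site corpora.  A second, partially
overlapping rule plants induced/inhibited regulatory types on the positive
sites so that transfer from the functional task provably helps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .curation import INDUCED_TAG, INHIBITED_TAG
from .graphs import contact_graph_adjacency, eigenvector_centrality
from .io import ProteinRecord, SiteRecord

_HELIX_RADIUS = 2.3     # Å
_HELIX_RISE = 1.5       # Å per residue
_HELIX_TWIST = 100.0    # degrees per residue
_STEP = 3.8             # Å consecutive Cα distance
_CLASH_DISTANCE = 3.0   # Å minimal non-adjacent Cα separation in coils

_HELIX_BIAS = "AALLEEQQKKRRIIVV"     # helix-former letter pool
_COIL_BIAS = "GGGPPPNNDDTTSSHH"      # coil/disorder-former letter pool
_ANCHOR_BIAS = "WWFFMM"              # core-packing (anchored) signature pool
_SITE_LETTERS = ("S", "T", "Y")
_SITE_LETTER_P = (0.55, 0.30, 0.15)


@dataclass
class SynthConfig:
    n_proteins: int = 200
    length_range: tuple[int, int] = (60, 150)
    helix_len_range: tuple[int, int] = (8, 20)
    coil_len_range: tuple[int, int] = (4, 14)
    plddt_helix: tuple[float, float] = (70.0, 95.0)
    plddt_coil: tuple[float, float] = (30.0, 60.0)
    site_density: float = 0.10       # fraction of eligible residues made S/T/Y
    min_site_spacing: int = 7        # residues between planted sites
    motif_prob: float = 0.35         # chance a site carries the ±3 motif
    anchor_prob: float = 0.5         # chance a segment packs against the core
    anchor_letter_prob: float = 0.45  # W/F/M draw rate inside anchored segments
    # planted logistic rule: (w_coil, w_centrality, w_motif, bias)
    functional_weights: tuple[float, float, float, float] = (5.0, 1.0, 1.5, -2.75)
    # regulatory-type rule shares centrality and motif but flips coil
    induced_weights: tuple[float, float, float, float] = (-2.0, 1.0, 1.5, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 < self.site_density <= 1:
            raise ValueError("site_density must be in (0, 1]")
        if not 0 <= self.motif_prob <= 1:
            raise ValueError("motif_prob must be a probability")
        for w in (*self.functional_weights, *self.induced_weights):
            if not np.isfinite(w):
                raise ValueError("planted weights must be finite")


@dataclass
class GroundTruth:
    """Per-site generative record: features, true probabilities, draws."""

    accession: list[str] = field(default_factory=list)
    position: list[int] = field(default_factory=list)
    coil: list[int] = field(default_factory=list)
    centrality: list[float] = field(default_factory=list)
    centrality_z: list[float] = field(default_factory=list)
    motif: list[int] = field(default_factory=list)
    functional_prob: list[float] = field(default_factory=list)
    functional_label: list[int] = field(default_factory=list)
    induced_prob: list[float] = field(default_factory=list)
    regulatory_label: list[str | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.accession)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(_HELIX_TWIST)
    return np.stack(
        [_HELIX_RADIUS * np.cos(t), _HELIX_RADIUS * np.sin(t), _HELIX_RISE * np.arange(n)],
        axis=1,
    )


_CORE_RADIUS = 8.0    # Å, anchored segments stay inside this sphere
_FAR_RADIUS = 16.0    # Å, unanchored segments head beyond this shell
_STEER = 2.0          # strength of the target steering vs isotropic noise


_SHELL_WIDTH = 8.0    # Å, unanchored segments live in [_FAR, _FAR + width]


def _steer_direction(
    position: np.ndarray, anchored: bool, rng: np.random.Generator
) -> np.ndarray:
    """Biased step direction: into the core sphere or into the shell band.

    The shell is bounded on both sides, so the chain never drifts out of
    reach of the core and anchored segments can always return.
    """
    dist = np.linalg.norm(position)
    radial = position / dist if dist > 1e-9 else rng.standard_normal(3)
    if anchored:
        target = -radial if dist > _CORE_RADIUS else rng.standard_normal(3)
    elif dist < _FAR_RADIUS:
        target = radial
    elif dist > _FAR_RADIUS + _SHELL_WIDTH:
        target = -radial
    else:
        target = rng.standard_normal(3)
    direction = _STEER * target + rng.standard_normal(3)
    return direction / np.linalg.norm(direction)


def _grow_backbone(
    segments: list[tuple[str, int, bool]], rng: np.random.Generator
) -> np.ndarray:
    """Chain segments together; helices are rigid, coils persistently random.

    Anchored segments steer into a compact core sphere around the origin
    (helices: best non-clashing placement closest to the core); unanchored
    segments steer out to the periphery.  Step length stays 3.8 Å
    throughout, non-adjacent residues keep >= 3 Å separation where the
    retry budget allows.
    """
    coords: list[np.ndarray] = []
    for kind, length, anchored in segments:
        if kind == "H":
            local = _helix_coords(length)
            candidates: list[tuple[float, np.ndarray]] = []
            for _ in range(40):
                seg = local @ _random_rotation(rng).T
                if coords:
                    direction = _steer_direction(coords[-1], anchored, rng)
                    seg = seg - seg[0] + coords[-1] + _STEP * direction
                    prev = np.asarray(coords)
                    body = seg[1:] if length > 1 else seg
                    if len(prev) > 1 and cdist(body, prev[:-1]).min() < _CLASH_DISTANCE:
                        continue
                mean_dist = float(np.linalg.norm(seg.mean(axis=0)))
                # anchored helices hug the core; unanchored sit in the shell
                score = (
                    mean_dist
                    if anchored
                    else abs(mean_dist - (_FAR_RADIUS + _SHELL_WIDTH / 2))
                )
                candidates.append((score, seg))
                if len(candidates) >= 10:
                    break
            if candidates:
                seg = min(candidates, key=lambda c: c[0])[1]
            coords.extend(seg)
        else:
            for _ in range(length):
                if not coords:
                    coords.append(np.zeros(3))
                    continue
                for _attempt in range(20):
                    step_dir = _steer_direction(coords[-1], anchored, rng)
                    candidate = coords[-1] + _STEP * step_dir
                    prev = np.asarray(coords[:-1])
                    if len(prev) == 0 or np.min(
                        np.linalg.norm(prev - candidate, axis=1)
                    ) >= _CLASH_DISTANCE:
                        break
                coords.append(candidate)
    return np.asarray(coords)


def generate_proteins(
    config: SynthConfig | None = None,
) -> tuple[list[ProteinRecord], dict]:
    """Generate toy proteins; returns records plus per-protein annotations.

    The second return value maps accession → dict with the generator's own
    per-residue segment labels ("H"/"C"), the planted site positions
    (1-based) and their motif indicators.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    proteins: list[ProteinRecord] = []
    meta: dict[str, dict] = {}
    helix_pool = np.array(list(_HELIX_BIAS))
    coil_pool = np.array(list(_COIL_BIAS))
    anchor_pool = np.array(list(_ANCHOR_BIAS))

    for p in range(config.n_proteins):
        target_len = int(rng.integers(*config.length_range))
        segments: list[tuple[str, int, bool]] = []
        kind = "H" if rng.random() < 0.5 else "C"
        total = 0
        while total < target_len:
            lo, hi = (
                config.helix_len_range if kind == "H" else config.coil_len_range
            )
            length = min(int(rng.integers(lo, hi + 1)), target_len - total)
            segments.append((kind, length, bool(rng.random() < config.anchor_prob)))
            total += length
            kind = "C" if kind == "H" else "H"
        coords = _grow_backbone(segments, rng)
        seg_labels = np.concatenate(
            [np.full(length, kind) for kind, length, _ in segments]
        )
        anchor_labels = np.concatenate(
            [np.full(length, anchored) for _, length, anchored in segments]
        )
        L = len(coords)

        seq = np.where(
            seg_labels == "H",
            rng.choice(helix_pool, size=L),
            rng.choice(coil_pool, size=L),
        )
        # anchored segments carry a hydrophobic/aromatic composition signature
        anchor_draw = anchor_labels & (rng.random(L) < config.anchor_letter_prob)
        seq[anchor_draw] = rng.choice(anchor_pool, size=int(anchor_draw.sum()))
        # plant candidate phosphosites with minimum spacing, away from ends
        eligible = np.arange(3, L - 1)
        rng.shuffle(eligible)
        n_sites = max(1, int(round(config.site_density * L)))
        site_idx: list[int] = []
        for i in eligible:
            if len(site_idx) >= n_sites:
                break
            if all(abs(i - j) >= config.min_site_spacing for j in site_idx):
                site_idx.append(int(i))
        site_idx.sort()
        motifs: list[int] = []
        for i in site_idx:
            seq[i] = rng.choice(_SITE_LETTERS, p=_SITE_LETTER_P)
            has_motif = int(rng.random() < config.motif_prob)
            if has_motif:
                seq[i - 3] = "R"
                seq[i + 1] = "P"
            motifs.append(has_motif)

        # pLDDT varies smoothly within a segment: one mean per segment plus
        # small per-residue jitter, the way real model confidence tracks
        # whole elements rather than flickering residue to residue
        plddt = np.empty(L)
        offset = 0
        for kind, length, _anchored in segments:
            lo, hi = config.plddt_helix if kind == "H" else config.plddt_coil
            center = 0.5 * (lo + hi) + rng.uniform(-3, 3)
            plddt[offset : offset + length] = np.clip(
                center + 2.0 * rng.standard_normal(length), lo, hi
            )
            offset += length
        sidechains = np.empty((L, 3))
        for i in range(L):
            if seq[i] == "G":
                sidechains[i] = np.nan
            else:
                offset = rng.standard_normal(3)
                sidechains[i] = coords[i] + offset / np.linalg.norm(offset)

        accession = f"SYN{p:04d}"
        proteins.append(
            ProteinRecord(
                accession=accession,
                sequence="".join(seq),
                ca_coords=coords,
                sidechain_centers=sidechains,
                plddt=plddt,
            )
        )
        meta[accession] = {
            "segments": "".join(seg_labels),
            "anchored": [bool(a) for a in anchor_labels],
            "site_positions": [i + 1 for i in site_idx],
            "site_motifs": motifs,
        }
    return proteins, meta


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def plant_labels(
    proteins: list[ProteinRecord],
    meta: dict,
    config: SynthConfig | None = None,
) -> tuple[list[SiteRecord], GroundTruth]:
    """Draw functional and regulatory labels from the planted logistic rules.

    Functional positives receive a "regulatory" annotation string (and the
    enzymatic-activity tag implied by their regulatory type) so the curation
    labeler reproduces the planted labels from annotations alone.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng([config.seed, 10007])

    # site-level generative features
    rows: list[tuple[str, int, int, float, int]] = []
    for protein in proteins:
        info = meta[protein.accession]
        adj = contact_graph_adjacency(protein)
        cent = eigenvector_centrality(adj)
        for position, motif in zip(info["site_positions"], info["site_motifs"]):
            coil = int(info["segments"][position - 1] == "C")
            rows.append((protein.accession, position, coil, cent[position - 1], motif))

    centralities = np.array([r[3] for r in rows])
    mu, sigma = centralities.mean(), centralities.std()
    sigma = sigma if sigma > 0 else 1.0

    wc, wz, wm, b = config.functional_weights
    wci, wzi, wmi, bi = config.induced_weights
    sites: list[SiteRecord] = []
    truth = GroundTruth()
    by_acc = {p.accession: p for p in proteins}
    for accession, position, coil, cent, motif in rows:
        z = (cent - mu) / sigma
        p_func = float(_sigmoid(wc * coil + wz * z + wm * motif + b))
        label = int(rng.random() < p_func)
        p_ind = float(_sigmoid(wci * coil + wzi * z + wmi * motif + bi))
        regulatory: str | None = None
        annotations: list[str] = []
        if label:
            annotations.append("regulatory")
            regulatory = "induced" if rng.random() < p_ind else "inhibited"
            annotations.append(
                INDUCED_TAG if regulatory == "induced" else INHIBITED_TAG
            )
        sites.append(
            SiteRecord(
                accession=accession,
                position=position,
                residue=by_acc[accession].residue_at(position),
                annotations=annotations,
                functional_label=label,
                regulatory_label=regulatory,
            )
        )
        truth.accession.append(accession)
        truth.position.append(position)
        truth.coil.append(coil)
        truth.centrality.append(cent)
        truth.centrality_z.append(float(z))
        truth.motif.append(motif)
        truth.functional_prob.append(p_func)
        truth.functional_label.append(label)
        truth.induced_prob.append(p_ind)
        truth.regulatory_label.append(regulatory)
    return sites, truth


def generate_dataset(
    config: SynthConfig | None = None,
) -> tuple[list[ProteinRecord], list[SiteRecord], GroundTruth]:
    """One-call generation of proteins, labeled sites and ground truth."""
    config = config or SynthConfig()
    proteins, meta = generate_proteins(config)
    sites, truth = plant_labels(proteins, meta, config)
    return proteins, sites, truth
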