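"""Synthetic molecule–receptor binding studies with planted, recoverable signal.

The generator emulates the statistical shape of a small odorant screen: a
dense molecule × receptor grid of log(EC50) values that is mostly zero
(roughly 8.7% positive pairs), positive values in a narrow continuous range,
and per-molecule odor-label sets whose community structure is driven by the
activation profile.

Binding is planted around a structure-odor relationship. Molecules are
drawn family-stratified from a curated odorant list and classified into six
structural families (aromatic, alicyclic, then acyclic carboxyl / aldehyde
/ ketone / other); receptors are split into six equal groups, each tuned to
one family, and every group member carries a characteristic sequence motif
(several copies of a group-specific trigram, the way real receptor
subfamilies share diagnostic motifs), so group identity is explicitly
encoded in the composition a model featurizes. The pair score sums the
molecule-family affinity (standardized closeness to each family's
fingerprint centroid, own family leading by a margin), a molecule main
effect, and a receptor popularity effect rank-balanced within groups so no
odor community is systematically more active, plus Gaussian noise of
standard deviation ``noise_sd`` (in units of the score's standard
deviation). Each molecule binds its top-scoring receptors; the binder
count is a deterministic molecular trait (promiscuity, an affine function
of a molecule latent with mean ``positive_rate * n_receptors``), so the
grid-level positive fraction matches ``positive_rate`` while binding stays
a learnable function of the descriptors. Binder log(EC50) is mapped
affinely from the score into a fixed range (default [3, 7]) so binder
strength is correlated with the same signal a model must learn.

Odor labels are generated from the *true* activation profile: a community is "present"
for a molecule when the group's share of the molecule's total activation
exceeds ``presence_share`` (the strongest group is always present), and the
molecule then draws several labels from its strongest community's
vocabulary plus at most one label from each other present community (so the
majority rule downstream is meaningful). A share threshold is a linear
functional of the profile, so the planted community rule is learnable by
the profile classifiers. A small
``label_noise_rate`` replaces labels uniformly at random. Molecules binding
nothing receive no labels, mirroring screens where some molecules have no
annotated odor.

Every quantity derives from a single seed through ``numpy.random.SeedSequence``
spawning, so sub-generators are independently reproducible and identical
seeds give byte-identical studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from ._odorants import ODORANT_SMILES
from .io import BindingSample, MoleculeRecord, ReceptorRecord
from .molfeats import canonical_smiles, morgan_fingerprint
from .protfeats import AMINO_ACIDS, kmer_proportions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale and noise parameters of the synthetic generator.

    Defaults mirror the screen the package targets: 63 molecules × 61
    receptors (3843 pairs), ≈333 positive pairs, 23 odor labels in six
    communities.
    """

    n_molecules: int = 63
    n_receptors: int = 61
    positive_rate: float = 333 / 3843
    n_odor_labels: int = 23
    n_communities: int = 6
    noise_sd: float = 0.3
    label_noise_rate: float = 0.01
    seed: int = 0
    receptor_length: tuple[int, int] = (290, 330)
    ec50_range: tuple[float, float] = (3.0, 7.0)
    presence_share: float = 0.30
    labels_from_majority: tuple[int, int] = (2, 4)
    secondary_label_prob: float = 0.25
    n_latent: int = 6
    selectivity_scale: float = 2.0
    mol_effect_scale: float = 0.25
    popularity_scale: float = 0.75
    motif_copies: tuple[int, int] = (4, 8)
    promiscuity_sd: float = 2.0
    max_retries: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must be in (0, 1)")
        if self.n_communities > self.n_odor_labels:
            raise ValueError("n_communities cannot exceed n_odor_labels")
        if self.n_molecules < 2 or self.n_receptors < self.n_communities:
            raise ValueError("study too small for the requested communities")


@dataclass
class SynthStudy:
    """A generated study plus the planted ground truth for recovery tests."""

    config: SynthConfig
    molecules: list[MoleculeRecord]
    receptors: list[ReceptorRecord]
    binding_samples: list[BindingSample]
    true_partition: dict[str, int]          # odor label -> community (1-based)
    true_assignments: dict[str, set[int]]   # molecule_id -> present communities
    majority_community: dict[str, int]      # molecule_id -> strongest community
    receptor_groups: dict[str, int]         # receptor_id -> community (1-based)

    def ground_truth(self) -> dict:
        """JSON-serializable ground truth bundle."""
        return {
            "true_partition": self.true_partition,
            "true_assignments": {
                m: sorted(c) for m, c in self.true_assignments.items()
            },
            "majority_community": self.majority_community,
            "receptor_groups": self.receptor_groups,
        }


def match_communities(
    learned: dict[str, int], reference: dict[str, int]
) -> dict[int, int]:
    """Map each learned community index to the reference community sharing
    the most labels (ties to the smaller reference index).

    Community indices are arbitrary on both sides, so recovery checks must
    align them by label overlap before comparing assignments.
    """
    overlap: dict[int, dict[int, int]] = {}
    for label, lc in learned.items():
        rc = reference.get(label)
        if rc is None:
            continue
        overlap.setdefault(lc, {})
        overlap[lc][rc] = overlap[lc].get(rc, 0) + 1
    return {
        lc: min(counts, key=lambda rc: (-counts[rc], rc))
        for lc, counts in overlap.items()
        if counts
    }


def _random_receptors(cfg: SynthConfig, rng: np.random.Generator
                      ) -> list[ReceptorRecord]:
    lo, hi = cfg.receptor_length
    width = len(str(cfg.n_receptors))
    receptors = []
    for i in range(cfg.n_receptors):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        receptors.append(ReceptorRecord(f"OR{i + 1:0{width}d}", seq))
    return receptors


#: structural families anchoring the planted structure-odor relationship,
#: matched in priority order (scaffold topology first — that is what
#: fingerprints encode most strongly — then acyclic functional groups)
FAMILY_NAMES: tuple[str, ...] = (
    "aromatic",      # any aromatic ring: benzenoids, phenols, pyrazines
    "alicyclic",     # non-aromatic ring: terpenoids, lactones, musks
    "carboxyl",      # acyclic esters and acids
    "aldehyde",      # acyclic aldehydes
    "ketone",        # acyclic ketones
    "other",         # acyclic alcohols, thiols, ethers, hydrocarbons
)


@lru_cache(maxsize=4096)
def family_of(smiles: str) -> int:
    """0-based structural-family index of a molecule (priority matching)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return 0
    if mol.GetRingInfo().NumRings() > 0:
        return 1
    for idx, smarts in ((2, "[CX3](=O)[OX2]"), (3, "[CX3H1]=O"),
                        (4, "[#6][CX3](=O)[#6]")):
        if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts)):
            return idx
    return 5


def _family_homolog(family: int, j: int) -> str:
    """Valid family-typical SMILES beyond the curated list (alkyl homologs)."""
    a, b = 2 + j % 7, 2 + j // 7
    builders = {
        0: lambda: "C" * (a + b) + "c1ccccc1",      # alkylbenzenes
        1: lambda: "C" * (a + b) + "C1CCCCC1",      # alkylcyclohexanes
        2: lambda: "C" * a + "OC(=O)" + "C" * b,    # esters
        3: lambda: "C" * (a + b) + "C=O",           # aldehydes
        4: lambda: "C" * a + "C(=O)" + "C" * b,     # ketones
        5: lambda: ("C" * (a + b) + "O") if j % 2 else ("C" * (a + b) + "S"),
    }
    return builders[family]()


def _pick_molecules(cfg: SynthConfig, rng: np.random.Generator
                    ) -> list[MoleculeRecord]:
    """Draw a family-stratified molecule panel from the curated odorants.

    Families are drawn round-robin so the panel covers the six functional
    classes evenly (screens are assembled to span chemistries); short pools
    are topped up with family-typical alkyl homologs.
    """
    n_fam = len(FAMILY_NAMES)
    pools: list[list[str]] = [[] for _ in range(n_fam)]
    for smi in rng.permutation(np.array(ODORANT_SMILES, dtype=object)):
        pools[family_of(str(smi))].append(str(smi))
    seen = {canonical_smiles(s) for s in ODORANT_SMILES}
    counters = [0] * n_fam
    chosen: list[str] = []
    fam_order = list(rng.permutation(n_fam))
    while len(chosen) < cfg.n_molecules:
        for fam in fam_order:
            if len(chosen) >= cfg.n_molecules:
                break
            if pools[fam]:
                chosen.append(pools[fam].pop(0))
                continue
            while True:  # top up with a fresh homolog of this family
                smi = _family_homolog(fam, counters[fam])
                counters[fam] += 1
                can = canonical_smiles(smi)
                if can not in seen and family_of(smi) == fam:
                    seen.add(can)
                    chosen.append(smi)
                    break
    width = len(str(cfg.n_molecules))
    return [
        MoleculeRecord(f"M{j + 1:0{width}d}", smi)
        for j, smi in enumerate(chosen)
    ]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _whiten(z: np.ndarray) -> np.ndarray:
    """Center and whiten so latent dimensions are uncorrelated unit-variance
    (keeps the planted group geometry symmetric)."""
    z = z - z.mean(axis=0)
    cov = np.cov(z, rowvar=False) + 1e-8 * np.eye(z.shape[1])
    return z @ np.linalg.inv(np.linalg.cholesky(cov)).T


def _latent(x: np.ndarray, d: int, rng: np.random.Generator) -> np.ndarray:
    proj = rng.normal(size=(x.shape[1], d)) / np.sqrt(x.shape[1])
    return _whiten(x @ proj)


def _family_affinity(
    smiles: list[str], fp: np.ndarray, n_groups: int
) -> np.ndarray:
    """Molecule-by-group affinity anchored to functional families.

    Each receptor group is tuned to one functional family of odorants
    (esters/carboxyls, aldehydes, ketones, aromatics, alcohols, the rest),
    the kind of structure-odor relationship a descriptor-based model can
    genuinely learn from a few dozen molecules. A molecule's affinity is
    its standardized closeness to each family's fingerprint centroid, with
    its own family leading by at least a modest margin so the primary odor
    community is well defined while graded affinity to the other families
    persists.
    """
    fams = np.array([family_of(s) % n_groups for s in smiles])
    centroids = np.vstack([
        fp[fams == c].mean(axis=0) if np.any(fams == c) else fp.mean(axis=0)
        for c in range(n_groups)
    ])
    dist = np.linalg.norm(fp[:, None, :] - centroids[None], axis=2)
    aff = _standardize(-dist)
    rows = np.arange(len(smiles))
    sorted_aff = np.sort(aff, axis=1)
    runner_up = np.where(
        np.argmax(aff, axis=1) == fams, sorted_aff[:, -2], aff.max(axis=1)
    )
    aff[rows, fams] = np.maximum(aff[rows, fams], runner_up + 0.25)
    return aff


def generate_study(config: SynthConfig) -> SynthStudy:
    """Generate a full synthetic study with ground truth.

    Retries with fresh sub-seeds (up to ``config.max_retries``) if the draw
    is degenerate — e.g. so many molecules bind nothing that odor labels
    would be too sparse to carry community structure — and raises if no
    feasible draw is found.
    """
    last_error: str | None = None
    for attempt in range(config.max_retries):
        study = _generate_once(config, attempt)
        n_unlabeled = sum(1 for m in study.molecules if not m.odor_labels)
        used_labels = set().union(*(m.odor_labels for m in study.molecules))
        if n_unlabeled > config.n_molecules // 2:
            last_error = f"{n_unlabeled}/{config.n_molecules} molecules unlabeled"
            continue
        if len(used_labels) < config.n_odor_labels * 0.8:
            last_error = f"only {len(used_labels)} odor labels realized"
            continue
        return study
    raise RuntimeError(
        f"no feasible study after {config.max_retries} attempts "
        f"(last problem: {last_error}); relax positive_rate or noise"
    )


def _generate_once(cfg: SynthConfig, attempt: int) -> SynthStudy:
    root = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(attempt,))
    rng_rec, rng_mol, rng_plant, rng_noise, rng_odor = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    receptors = _random_receptors(cfg, rng_rec)
    molecules = _pick_molecules(cfg, rng_mol)

    # receptor groups: random but near-equal-sized; every member carries a
    # group-specific trigram motif so group identity is encoded in the
    # sequence composition the featurizers see
    group_of = np.empty(cfg.n_receptors, dtype=int)
    group_of[rng_plant.permutation(cfg.n_receptors)] = (
        np.arange(cfg.n_receptors) % cfg.n_communities
    )
    motifs: list[str] = []
    while len(motifs) < cfg.n_communities:
        cand = "".join(rng_plant.choice(list(AMINO_ACIDS), size=3))
        if cand not in motifs:
            motifs.append(cand)
    for j, rec in enumerate(receptors):
        seq = list(rec.sequence)
        motif = motifs[group_of[j]]
        for _ in range(int(rng_plant.integers(*cfg.motif_copies))):
            pos = int(rng_plant.integers(0, len(seq) - 3))
            seq[pos:pos + 3] = motif
        receptors[j] = ReceptorRecord(rec.receptor_id, "".join(seq),
                                      rec.species_tag)

    # latent spaces of the planted bilinear score
    d = max(cfg.n_latent, cfg.n_communities)
    fp = morgan_fingerprint(molecules).values
    comp = np.vstack([kmer_proportions(r.sequence, 1) for r in receptors])
    aff_groups = _family_affinity(
        [m.smiles for m in molecules], fp, cfg.n_communities
    )
    f = _latent(fp, d, rng_plant)       # molecules × d (main effects only)
    g = _latent(comp, d, rng_plant)     # receptors × d
    u = rng_plant.normal(size=d) / np.sqrt(d)
    v = rng_plant.normal(size=d) / np.sqrt(d)
    u_k = rng_plant.normal(size=d) / np.sqrt(d)
    affinity = aff_groups[:, group_of]  # molecules × receptors

    # receptor popularity: monotone in the latent main effect but
    # rank-balanced within groups, so every odor community holds the same
    # popularity spectrum and none is systematically more active
    raw_pop = g @ v
    popularity = np.empty(cfg.n_receptors)
    for c in range(cfg.n_communities):
        members = np.flatnonzero(group_of == c)
        ranks = np.argsort(np.argsort(raw_pop[members], kind="stable"))
        popularity[members] = norm.ppf((ranks + 1) / (len(members) + 1))

    score = (
        cfg.selectivity_scale * affinity
        + cfg.mol_effect_scale * (f @ u)[:, None]
        + cfg.popularity_scale * popularity[None, :]
    )
    score = (score - score.mean()) / score.std()
    noisy = score + cfg.noise_sd * rng_noise.normal(size=score.shape)

    # each molecule binds its top-k receptors; promiscuity k is a
    # deterministic molecular trait, so it can in principle be learned
    lam = cfg.positive_rate * cfg.n_receptors
    k_per_mol = np.clip(
        np.rint(lam + cfg.promiscuity_sd * (f @ u_k)).astype(int),
        0,
        min(cfg.n_receptors, int(2.5 * lam) + 1),
    )
    binder = np.zeros_like(noisy, dtype=bool)
    for i in range(cfg.n_molecules):
        if k_per_mol[i] > 0:
            binder[i, np.argsort(noisy[i])[-k_per_mol[i]:]] = True

    lo, hi = cfg.ec50_range
    if binder.any():
        smin, smax = np.quantile(noisy[binder], [0.01, 0.99])
        stretch = max(smax - smin, 1e-9)
        strength = np.clip((noisy - smin) / stretch, 0.0, 1.0)
        log_ec50 = np.where(binder, lo + strength * (hi - lo), 0.0)
    else:
        log_ec50 = np.zeros_like(noisy)

    samples = [
        BindingSample(m.molecule_id, r.receptor_id, float(log_ec50[i, j]))
        for i, m in enumerate(molecules)
        for j, r in enumerate(receptors)
    ]

    receptor_groups = {
        r.receptor_id: int(group_of[j]) + 1 for j, r in enumerate(receptors)
    }
    group_sums = np.zeros((cfg.n_molecules, cfg.n_communities))
    for c in range(cfg.n_communities):
        group_sums[:, c] = log_ec50[:, group_of == c].sum(axis=1)
    totals = group_sums.sum(axis=1)
    shares = np.divide(
        group_sums, totals[:, None],
        out=np.zeros_like(group_sums), where=totals[:, None] > 0,
    )
    presence = shares > cfg.presence_share
    # the strongest group of any binder is always present
    binder_rows = np.flatnonzero(totals > 0)
    presence[binder_rows, np.argmax(group_sums[binder_rows], axis=1)] = True

    # label vocabulary split round-robin over communities
    labels = [f"odor{i + 1:02d}" for i in range(cfg.n_odor_labels)]
    true_partition = {lab: (i % cfg.n_communities) + 1 for i, lab in enumerate(labels)}
    vocab_of = {
        c: [lab for lab in labels if true_partition[lab] == c]
        for c in range(1, cfg.n_communities + 1)
    }

    true_assignments: dict[str, set[int]] = {}
    majority: dict[str, int] = {}
    k_lo, k_hi = cfg.labels_from_majority
    for i, mol in enumerate(molecules):
        present = {int(c) + 1 for c in np.flatnonzero(presence[i])}
        true_assignments[mol.molecule_id] = present
        if not present:
            continue
        strongest = int(np.argmax(group_sums[i])) + 1
        if strongest not in present:  # pragma: no cover - argmax is present by construction
            strongest = min(present)
        majority[mol.molecule_id] = strongest
        vocab = vocab_of[strongest]
        k = int(rng_odor.integers(k_lo, k_hi + 1))
        majority_labels = [
            str(s)
            for s in rng_odor.choice(vocab, size=min(k, len(vocab)), replace=False)
        ]
        # overlapping communities co-occur through a characteristic pair of
        # notes, fixed per (unordered) community pair, mirroring how real
        # vocabularies are bridged by the same popular descriptors; a
        # bridged molecule carries exactly that pair, so repeated overlap
        # reinforces one co-annotation edge instead of accumulating many
        bridge_labels: list[str] = []
        for c in sorted(present - {strongest}):
            if rng_odor.random() < cfg.secondary_label_prob:
                a, b = min(strongest, c), max(strongest, c)
                lab_a = vocab_of[a][b % len(vocab_of[a])]
                lab_b = vocab_of[b][a % len(vocab_of[b])]
                bridge_labels += [lab_a, lab_b]
        chosen = bridge_labels if bridge_labels else majority_labels
        final = set()
        for lab in chosen:
            if rng_odor.random() < cfg.label_noise_rate:
                lab = str(rng_odor.choice(labels))
            final.add(str(lab))
        mol.odor_labels = final

    return SynthStudy(
        config=cfg,
        molecules=molecules,
        receptors=receptors,
        binding_samples=samples,
        true_partition=true_partition,
        true_assignments=true_assignments,
        majority_community=majority,
        receptor_groups=receptor_groups,
    )
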