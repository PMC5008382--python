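"""Synthetic urine-EV small-RNA cohorts with planted isomiR effects.

The generator produces everything the pipeline consumes — FASTQ reads,
count matrices, Ct tables, PSA values and truth labels — with the
statistical structure the analysis assumes:

* a two-group cohort (discovery preset 4 control vs 9 cancer; validation
  preset 26 vs 48);
* per-miRNA abundances that are lognormal across miRNAs, split into six
  end-variant isoforms (mature, -1 and -2 trimming, +1 templated
  elongation, NTA-U, NTA-A) by Dirichlet-sampled proportions;
* negative-binomial counts (variance mu + phi*mu^2);
* planted relative effects: the 23-nt (+1 elongation) miR-204-like isoform
  increased 3-fold in cancer while its mature form stays flat, and the
  trimmed miR-21-like / miR-375-like isomiRs decreased 4-fold;
* a globally reduced miRNA library yield in cancer samples;
* lognormal serum PSA with partial group separation, and Ct values that
  are affine in log2 expression plus Gaussian cycle noise.

Everything is driven by one integer seed; regeneration with the same seed
is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER
from .quantify import CountMatrix
from .refdb import MatureAnnotation, ReferenceSet
from . import qpcr as _qpcr

#: The three named hairpin fixtures hosting the panel miRNAs.  Matures are
#: embedded with 4-nt flanks; the 3' flank's first base makes the panel
#: isomiRs classifiable (G continuation for miR-204's 23-nt templated
#: elongation) and keeps NTA-U/NTA-A non-templated on every fixture.
FIXTURE_HAIRPINS: tuple[tuple[str, str, str, str, str], ...] = (
    ("mir-21-like", "miR-21-5p", "UAGCUUAUCAGACUGAUGUUGA", "AAAA", "GGGG"),
    ("mir-204-like", "miR-204-5p", "UUCCCUUUGUCAUCCUAUGCCU", "AAAA", "GAGA"),
    ("mir-375-like", "miR-375", "UUUGUUCGUUCGGCUCGCGUGA", "AAAA", "CCGA"),
)

ISOFORM_CATEGORIES = ("mature", "trim1", "trim2", "elong1", "NTA-U", "NTA-A")

#: (mirna_id, isoform category, fold multiplier on the cancer-group
#: proportion).  The defaults plant the panel's signal: the miR-204-like
#: 23-nt elongation up 3-fold, the trimmed miR-21/miR-375-like isomiRs
#: down 4-fold.
DEFAULT_PLANTED_EFFECTS: tuple[tuple[str, str, float], ...] = (
    ("miR-204-5p", "elong1", 3.0),
    ("miR-21-5p", "trim2", 0.25),
    ("miR-375", "trim1", 0.25),
)

#: Panel assay -> (mirna_id, isoform category) mapping used by the qPCR
#: simulator: mature assays target the exact mature sequence; isomiR
#: assays target the planted end-variants they were designed against.
DEFAULT_ASSAY_TARGETS: dict[str, tuple[str, str]] = {
    "miR-21-5p": ("miR-21-5p", "mature"),
    "miR-204-5p": ("miR-204-5p", "mature"),
    "miR-375": ("miR-375", "mature"),
    _qpcr.ISOMIR_ASSAYS[0]: ("miR-21-5p", "trim2"),
    _qpcr.ISOMIR_ASSAYS[1]: ("miR-204-5p", "elong1"),
    _qpcr.ISOMIR_ASSAYS[2]: ("miR-375", "trim1"),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the discovery preset: 4 control vs 9 cancer
    samples, NB dispersion 0.2, a 0.7 global miRNA-yield scale in cancer,
    the three planted panel effects, and lognormal PSA tuned so PSA alone
    discriminates only partially (AUC near 0.7 in large-sample
    expectation).
    """

    n_control: int = 4
    n_cancer: int = 9
    n_mirnas: int = 30
    reads_per_sample: int = 20000
    dispersion: float = 0.2
    isomir_dirichlet: tuple[float, ...] = (10.0, 3.0, 1.5, 2.0, 2.0, 1.5)
    fixture_boost: float = 5.0
    planted_effects: tuple[tuple[str, str, float], ...] = DEFAULT_PLANTED_EFFECTS
    global_cancer_scale: float = 0.7
    psa_lognormal: tuple[float, float, float] = (1.80, 2.47, 0.90)
    ct_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_cancer) < 1:
            raise ValueError("cohort sizes must be positive")
        if self.n_mirnas < len(FIXTURE_HAIRPINS):
            raise ValueError(f"n_mirnas must be >= {len(FIXTURE_HAIRPINS)}")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.isomir_dirichlet) != len(ISOFORM_CATEGORIES):
            raise ValueError(
                f"isomir_dirichlet needs {len(ISOFORM_CATEGORIES)} concentrations"
            )
        if any(f <= 0 for _, _, f in self.planted_effects):
            raise ValueError("planted fold changes must be > 0")
        if self.fixture_boost < 1:
            raise ValueError("fixture_boost must be >= 1")
        if not (0 < self.global_cancer_scale <= 1):
            raise ValueError("global_cancer_scale must be in (0, 1]")
        if self.psa_lognormal[2] <= 0:
            raise ValueError("PSA sigma must be > 0")


VALIDATION_PRESET = dict(n_control=26, n_cancer=48)


def validation_config(seed: int = 0, **overrides) -> SimConfig:
    """The 26-control vs 48-cancer qPCR validation preset."""
    kw = dict(VALIDATION_PRESET)
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


# ---------------------------------------------------------------------------
# reference fixture


def make_toy_reference(seed: int = 0, n_mirnas: int = 3) -> ReferenceSet:
    """Three fixed panel-like hairpins plus random decoys.

    Decoy hairpins carry a 22-nt mature with 4-nt flanks; the 3' flank
    starts with G or C so that +1 elongation, NTA-U and NTA-A are always
    decidable against the template.  Fixtures are identical across seeds;
    decoys vary with the seed.
    """
    rng = np.random.default_rng(seed)
    hairpins: dict[str, str] = {}
    matures: list[MatureAnnotation] = []
    for hairpin_id, mirna_id, canonical, flank5, flank3 in FIXTURE_HAIRPINS:
        hairpins[hairpin_id] = flank5 + canonical + flank3
        matures.append(
            MatureAnnotation(
                mirna_id=mirna_id,
                hairpin_id=hairpin_id,
                start=len(flank5),
                end=len(flank5) + len(canonical),
                arm="5p",
            )
        )
    bases = np.array(list("ACGU"))
    anchor_bases = np.array(list("GC"))
    for i in range(n_mirnas - len(FIXTURE_HAIRPINS)):
        flank5 = "".join(rng.choice(bases, size=4))
        mature = "".join(rng.choice(bases, size=22))
        flank3 = "".join(rng.choice(anchor_bases, size=1)) + "".join(
            rng.choice(bases, size=3)
        )
        hid = f"toy-mir-{i + 1:03d}"
        hairpins[hid] = flank5 + mature + flank3
        matures.append(
            MatureAnnotation(
                mirna_id=f"toy-miR-{i + 1:03d}", hairpin_id=hid, start=4, end=26, arm="5p"
            )
        )
    return ReferenceSet(hairpins=hairpins, matures=matures)


def isoform_sequence(ref: ReferenceSet, mirna_id: str, category: str) -> str:
    """Construct the read sequence of one isoform category on its hairpin."""
    ann = ref.mature(mirna_id)
    hp = ref.hairpins[ann.hairpin_id]
    canonical = hp[ann.start : ann.end]
    if category == "mature":
        return canonical
    if category == "trim1":
        return canonical[:-1]
    if category == "trim2":
        return canonical[:-2]
    if category == "elong1":
        if ann.end >= len(hp):
            raise ValueError(
                f"{mirna_id}: +1 elongation not constructible (no 3' flank)"
            )
        return canonical + hp[ann.end]
    if category in ("NTA-U", "NTA-A"):
        base = category[-1]
        if ann.end < len(hp) and hp[ann.end] == base:
            raise ValueError(
                f"{mirna_id}: {category} not constructible (templated {base} follows)"
            )
        return canonical + base
    raise ValueError(f"unknown isoform category {category!r}")


def isoform_key(ref: ReferenceSet, mirna_id: str, category: str) -> str:
    """The quantify-level feature key mirna|d5|d3|tail of one category."""
    d3 = {"mature": 0, "trim1": -1, "trim2": -2, "elong1": 1, "NTA-U": 0, "NTA-A": 0}[
        category
    ]
    tail = category[-1] if category.startswith("NTA-") else ""
    return f"{mirna_id}|0|{d3}|{tail}"


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SyntheticCohort:
    """A generated cohort: truth table, clinical table, optional FASTQ."""

    sample_ids: list[str]
    clinical: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig
    fastq_paths: dict[str, Path] = field(default_factory=dict)
    proportions: pd.DataFrame | None = None  # miRNA x isoform-category split

    @property
    def labels(self) -> pd.Series:
        return self.clinical.set_index("sample_id")["label"]

    @property
    def groups(self) -> pd.Series:
        return self.labels.map({0: "control", 1: "cancer"})

    def provenance(self) -> dict:
        return {"config": asdict(self.config)}


def simulate_cohort(
    cfg: SimConfig,
    ref: ReferenceSet,
    out_dir: str | Path | None = None,
    emit_fastq: bool = True,
    adapter: str = DEFAULT_ADAPTER,
) -> SyntheticCohort:
    """Generate a two-group cohort from a SimConfig.

    Per sample and miRNA the six isoform means are
    ``lib_size * weight_mirna * proportion_isoform``; in cancer samples the
    planted isoform proportions are multiplied by their fold (without
    renormalizing, so the planted fold is exact on that isoform) and the
    library size is scaled by ``global_cancer_scale``.  Counts are NB via
    gamma-Poisson mixing.  With ``emit_fastq`` the reads (plus 3' adapter,
    constant Phred-40 quality) are written one file per sample.

    The three panel fixtures emulate the selection the study design
    presumes — highly abundant miRNAs whose end-variants are major
    isoforms: their lognormal weight is multiplied by ``fixture_boost``
    and their isoform split is the Dirichlet mean rather than a random
    draw (decoys keep sampled splits).
    """
    mirna_ids = ref.mirna_ids[: cfg.n_mirnas]
    if len(mirna_ids) < cfg.n_mirnas:
        raise ValueError(
            f"reference provides {len(mirna_ids)} miRNAs, config wants {cfg.n_mirnas}"
        )
    planted = {(m, c): f for m, c, f in cfg.planted_effects}
    for m, c in planted:
        isoform_sequence(ref, m, c)  # raises if not constructible

    rng = np.random.default_rng(cfg.seed)
    n_m = len(mirna_ids)
    fixture_names = {mid for _, mid, _, _, _ in FIXTURE_HAIRPINS}
    is_fixture = np.array([m in fixture_names for m in mirna_ids])
    weights = np.exp(rng.normal(0.0, 1.2, size=n_m))
    weights[is_fixture] *= cfg.fixture_boost
    weights /= weights.sum()
    alphas = np.asarray(cfg.isomir_dirichlet, dtype=float)
    proportions = rng.dirichlet(alphas, size=n_m)
    proportions[is_fixture] = alphas / alphas.sum()

    sample_ids = [f"ctrl-{i + 1:02d}" for i in range(cfg.n_control)] + [
        f"case-{i + 1:02d}" for i in range(cfg.n_cancer)
    ]
    labels = np.array([0] * cfg.n_control + [1] * cfg.n_cancer)
    lib_factor = rng.uniform(0.7, 1.3, size=len(sample_ids))

    seqs = {
        (m, c): isoform_sequence(ref, m, c) for m in mirna_ids for c in ISOFORM_CATEGORIES
    }
    rows = []
    for s_idx, sid in enumerate(sample_ids):
        cancer = labels[s_idx] == 1
        lib = cfg.reads_per_sample * lib_factor[s_idx] * (
            cfg.global_cancer_scale if cancer else 1.0
        )
        mu_sample = np.empty((n_m, len(ISOFORM_CATEGORIES)))
        for mi, m in enumerate(mirna_ids):
            for ci, c in enumerate(ISOFORM_CATEGORIES):
                p = proportions[mi, ci]
                if cancer and (m, c) in planted:
                    p = p * planted[(m, c)]
                mu_sample[mi, ci] = lib * weights[mi] * p
        if cfg.dispersion > 0:
            lam = rng.gamma(
                shape=1.0 / cfg.dispersion, scale=cfg.dispersion * mu_sample
            )
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu_sample)
        total_mu = mu_sample.sum()
        for mi, m in enumerate(mirna_ids):
            for ci, c in enumerate(ISOFORM_CATEGORIES):
                rows.append(
                    {
                        "sample_id": sid,
                        "group": "cancer" if cancer else "control",
                        "mirna_id": m,
                        "category": c,
                        "isoform_key": isoform_key(ref, m, c),
                        "sequence": seqs[(m, c)],
                        "count": int(counts[mi, ci]),
                        "expected_count": mu_sample[mi, ci],
                        "true_rpm": mu_sample[mi, ci] / total_mu * 1e6,
                    }
                )
    truth = pd.DataFrame(rows)

    mu0, mu1, sigma = cfg.psa_lognormal
    psa = np.where(
        labels == 1,
        rng.lognormal(mu1, sigma, size=len(sample_ids)),
        rng.lognormal(mu0, sigma, size=len(sample_ids)),
    )
    clinical = pd.DataFrame(
        {"sample_id": sample_ids, "label": labels, "psa": np.round(psa, 3)}
    )

    fastq_paths: dict[str, Path] = {}
    if emit_fastq:
        if out_dir is None:
            raise ValueError("out_dir required when emit_fastq=True")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        adapter_dna = adapter.upper().replace("U", "T")
        for sid in sample_ids:
            path = out_dir / f"{sid}.fastq"
            sub = truth[truth["sample_id"] == sid]
            with open(path, "w") as fh:
                serial = 0
                for row in sub.itertuples(index=False):
                    read = row.sequence.replace("U", "T") + adapter_dna
                    qual = "I" * len(read)
                    for _ in range(row.count):
                        serial += 1
                        fh.write(f"@{sid}:{serial}\n{read}\n+\n{qual}\n")
            fastq_paths[sid] = path
    return SyntheticCohort(
        sample_ids=sample_ids,
        clinical=clinical,
        truth=truth,
        config=cfg,
        fastq_paths=fastq_paths,
        proportions=pd.DataFrame(
            proportions, index=pd.Index(mirna_ids, name="mirna_id"), columns=ISOFORM_CATEGORIES
        ),
    )


def simulate_qpcr(
    cohort: SyntheticCohort,
    assays: Mapping[str, tuple[str, str]] | None = None,
    ct_noise_sd: float | None = None,
    c0: float = 38.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stem-loop qPCR emulation over the cohort's truth expression.

    ``Ct = c0 - log2(true RPM + 1) + Normal(0, ct_noise_sd)`` per (sample,
    assay), so each doubling of target abundance lowers Ct by one cycle.
    Returns (CtTable, ClinicalTable).
    """
    if assays is None:
        assays = DEFAULT_ASSAY_TARGETS
    if ct_noise_sd is None:
        ct_noise_sd = cohort.config.ct_noise_sd
    if seed is None:
        seed = cohort.config.seed + 7919
    rng = np.random.default_rng(seed)

    truth = cohort.truth.set_index(["sample_id", "mirna_id", "category"])
    rows = []
    for sid in cohort.sample_ids:
        for assay_id, (mirna_id, category) in assays.items():
            try:
                rpm = truth.loc[(sid, mirna_id, category), "true_rpm"]
            except KeyError:
                raise ValueError(
                    f"assay {assay_id!r} targets ({mirna_id}, {category}) "
                    "absent from cohort truth"
                ) from None
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample_id": sid,
                    "assay_id": assay_id,
                    "ct": c0 - np.log2(rpm + 1.0) + noise,
                }
            )
    return pd.DataFrame(rows), cohort.clinical.copy()


# ---------------------------------------------------------------------------
# count-level simulation (for differential-test studies)


def simulate_count_matrix(
    n_features: int = 2000,
    n_control: int = 4,
    n_cancer: int = 9,
    phi: float = 0.2,
    n_planted: int = 0,
    planted_fold: float = 0.25,
    planted_class: str = "trimming",
    mean_log: float = np.log(150.0),
    mean_sd: float = 1.2,
    min_planted_mean: float = 50.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """NB count matrix with optional planted fold changes.

    A direct feature-level generator for calibration and power studies:
    feature baseline means are lognormal, library sizes vary moderately,
    counts are NB(mu, phi).  ``n_planted`` features (sampled among those
    with baseline mean >= ``min_planted_mean``, i.e. the abundance range a
    count-based test can realistically see) get their cancer-group mean
    multiplied by ``planted_fold`` and are labelled ``planted_class`` in
    the feature metadata; all other features draw a variant class at
    random.  Returns (CountMatrix, groups, truth table).
    """
    rng = np.random.default_rng(seed)
    n = n_control + n_cancer
    sample_ids = [f"ctrl-{i + 1:02d}" for i in range(n_control)] + [
        f"case-{i + 1:02d}" for i in range(n_cancer)
    ]
    groups = pd.Series(
        ["control"] * n_control + ["cancer"] * n_cancer, index=sample_ids
    )
    base = rng.lognormal(mean_log, mean_sd, size=n_features)
    lib = rng.uniform(0.7, 1.3, size=n)

    eligible = np.flatnonzero(base >= min_planted_mean)
    if n_planted > len(eligible):
        raise ValueError(
            f"only {len(eligible)} features reach mean {min_planted_mean}, "
            f"cannot plant {n_planted}"
        )
    planted_idx = np.sort(rng.choice(eligible, size=n_planted, replace=False))
    fold = np.ones(n_features)
    fold[planted_idx] = planted_fold

    is_cancer = (groups == "cancer").values
    mu = base[:, None] * lib[None, :]
    mu[:, is_cancer] *= fold[:, None]
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    feature_ids = [f"feat-{i + 1:05d}" for i in range(n_features)]
    other_classes = np.array(
        ["mature", "elongation", "NTA-U", "NTA-A", "fiveprime_mod"]
    )
    classes = rng.choice(other_classes, size=n_features)
    classes[planted_idx] = planted_class
    data = pd.DataFrame(
        counts, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids
    )
    meta = pd.DataFrame(
        {
            "mirna_id": feature_ids,
            "d5": 0,
            "d3": 0,
            "nta_tail": "",
            "variant_class": classes,
        },
        index=data.index,
    )
    truth = pd.DataFrame(
        {
            "baseline_mean": base,
            "fold": fold,
            "planted": fold != 1.0,
            "variant_class": classes,
        },
        index=data.index,
    )
    cm = CountMatrix(data=data, level="isoform", feature_meta=meta)
    return cm, groups, truth
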