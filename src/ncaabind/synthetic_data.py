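"""Synthetic IEDB-style exports with a known generative model.

The generator emulates the filtered affinity export the pipeline consumes:
9/10-mer peptides each carrying at least one NCAA, IC50 values in nM drawn
from a linear model in the assembled peptide feature space
(``y = x @ beta + intercept + noise`` on the log10 scale, IC50 = 10^y
clamped to the 0.1–65,000 nM range of real exports), plus distractor rows
that each violate exactly one filter rule (no NCAA, missing quantitative
value, wrong HLA, wrong response type).  Everything is deterministic given
the seed, so full-pipeline statistical recovery can be tested without any
database access.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .chem_encoder import (
    TokenRegistry,
    build_token_map,
    default_registry,
    descriptor_matrix,
    encode_peptide,
    fit_reducer,
)
from .notation import Modification, ModifiedPeptide, render_epitope_name, tokenize

__all__ = ["GenerativeSpec", "GroundTruth", "make_registry", "generate"]

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
IC50_MIN_NM = 0.1
IC50_MAX_NM = 65000.0
EXPORT_COLUMNS = [
    "Name",
    "Qualitative Measurement",
    "Quantitative Measurement",
    "Response Measured",
    "HLA",
    "Epitope IRI",
]


@dataclass(frozen=True)
class GenerativeSpec:
    """Study conditions for one synthetic export.

    ``target_r2`` is the intended generative R² (signal variance over total
    variance); the noise standard deviation is derived from it unless
    ``noise_sd`` is given explicitly.  ``signal_sd``/``signal_mean`` set the
    spread and centre of the noiseless log10(IC50) so that, at the defaults,
    essentially no record hits the clamp range.

    Records are organised as analog series: ``n_scaffolds`` parent
    sequences are drawn and every record is an NCAA-modified variant of one
    parent, with a ``replicate_rate`` fraction of records re-measuring an
    earlier variant with fresh assay noise — mirroring how affinity
    datasets for modified epitopes are actually assembled (a few parent
    epitopes, systematically modified, with replicate assays).  With few
    parents the encoded features concentrate on a handful of latent
    directions, the regime a few-component PLS model is designed for.

    Unless explicit ``coefficients`` are supplied, the drawn coefficient
    vector puts random position-specific weights on the leading reduced
    chemical axis of each residue position, so affinity depends on the
    dominant physicochemical character of the residues and on where along
    the peptide they sit.
    """

    n_records: int = 166
    length_weights: dict[int, float] = field(
        default_factory=lambda: {9: 0.5, 10: 0.5}
    )
    n_ncaa_tokens: int = 28
    mods_per_peptide: dict[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.2}
    )
    n_scaffolds: int = 4
    replicate_rate: float = 0.2
    coefficients: np.ndarray | None = None
    noise_sd: float | None = None
    target_r2: float = 0.5
    signal_sd: float = 0.7
    signal_mean: float = 1.8
    distractors: dict[str, int] = field(
        default_factory=lambda: {
            "no_ncaa": 10,
            "missing_quantitative": 10,
            "wrong_hla": 10,
            "wrong_response": 10,
        }
    )
    hla_allele: str = "HLA-A*02:01"
    response_measured: str = "half maximal inhibitory concentration (IC50)"
    d: int = 10
    L_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 10:
            raise ValueError("n_records must be >= 10")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.target_r2 <= 1:
            raise ValueError("target_r2 must be in (0, 1]")
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if not 0 <= self.replicate_rate < 1:
            raise ValueError("replicate_rate must be in [0, 1)")
        if any(v < 0 for v in self.distractors.values()):
            raise ValueError("distractor counts must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew: coefficients, noiseless targets, realized R²."""

    coefficients: np.ndarray
    intercept: float
    noise_sd: float
    y_noiseless: np.ndarray  # aligned with post-filter record order
    y: np.ndarray  # noisy pre-clamp log10(IC50)
    realized_r2: float
    n_clamped: int
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "y_noiseless": self.y_noiseless.tolist(),
            "y": self.y.tolist(),
            "realized_r2": self.realized_r2,
            "n_clamped": self.n_clamped,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def make_registry(n_ncaa: int, seed: int = 0) -> TokenRegistry:
    """Canonical 20 plus ``n_ncaa`` NCAAs sampled from the packaged pool."""
    full = default_registry(include_ncaa_pool=True)
    pool = [t for t in full.tokens if "-" in t]
    if not 0 <= n_ncaa <= len(pool):
        raise ValueError(f"n_ncaa must be in 0..{len(pool)}, got {n_ncaa}")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(pool, size=n_ncaa, replace=False)) if n_ncaa else set()
    keep = [t for t in full.tokens if "-" not in t or t in chosen]
    return TokenRegistry(
        {t: full.entries[t] for t in keep},
        {t: full.provenance[t] for t in keep if t in full.provenance},
    )


def _sample_from_weights(rng: np.random.Generator, weights: dict[int, float], size: int):
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=size, p=probs)


def _sample_variant(
    rng: np.random.Generator,
    scaffold: str,
    n_mods: int,
    ncaa_tokens: list[str],
) -> ModifiedPeptide:
    """An NCAA-modified variant of a parent scaffold sequence.

    Modified positions take the letter the chosen NCAA code applies to, so
    every chosen modification admits a valid site by construction.
    """
    letters = list(scaffold)
    n_mods = min(n_mods, len(ncaa_tokens), len(letters))
    positions = rng.choice(len(letters), size=n_mods, replace=False) + 1
    chosen = rng.choice(ncaa_tokens, size=n_mods, replace=False)
    mods = []
    for pos, tok in zip(positions, chosen):
        letter, code = tok.split("-", 1)
        letters[pos - 1] = letter
        mods.append(Modification(code, letter, int(pos)))
    return ModifiedPeptide(
        "".join(letters), tuple(sorted(mods, key=lambda m: m.position))
    )


def _qualitative_label(ic50_nm: float) -> str:
    if ic50_nm < 50:
        return "Positive-High"
    if ic50_nm < 500:
        return "Positive-Intermediate"
    if ic50_nm < 5000:
        return "Positive-Low"
    return "Negative"


def generate(
    spec: GenerativeSpec,
    registry: TokenRegistry | None = None,
    out_path=None,
) -> tuple[list[dict[str, str]], GroundTruth]:
    """Draw a synthetic export under ``spec`` and optionally write it as CSV.

    Returns the shuffled rows (dicts in the export column schema) and the
    :class:`GroundTruth`, whose target arrays align with the order in which
    the non-distractor rows appear in the written file — i.e. with the
    record order after the filter cascade.
    """
    registry = registry or make_registry(spec.n_ncaa_tokens, seed=spec.seed)
    ncaa_tokens = [t for t in registry.tokens if "-" in t]
    if not ncaa_tokens:
        raise ValueError("registry has no NCAA tokens; records could not pass filters")
    rng = np.random.default_rng(spec.seed)

    # reference encoder fitted on the registry
    reducer = fit_reducer(descriptor_matrix(registry), d=spec.d)
    token_map = build_token_map(registry, reducer)

    # parent scaffolds, then analog-series records (variants + replicates)
    scaffold_lengths = _sample_from_weights(rng, spec.length_weights, spec.n_scaffolds)
    scaffolds = [
        "".join(rng.choice(list(CANONICAL), size=int(L))) for L in scaffold_lengths
    ]
    peptides: list[ModifiedPeptide] = []
    for _ in range(spec.n_records):
        if peptides and rng.random() < spec.replicate_rate:
            peptides.append(peptides[rng.integers(0, len(peptides))])
        else:
            scaffold = scaffolds[rng.integers(0, spec.n_scaffolds)]
            m = int(_sample_from_weights(rng, spec.mods_per_peptide, 1)[0])
            peptides.append(_sample_variant(rng, scaffold, m, ncaa_tokens))
    X = np.vstack(
        [
            encode_peptide(tokenize(p), token_map, L_max=spec.L_max, d=spec.d)
            for p in peptides
        ]
    )

    if spec.coefficients is not None:
        beta = np.asarray(spec.coefficients, dtype=float)
        if beta.size != X.shape[1]:
            raise ValueError("coefficients length must equal the feature dimension")
        intercept = spec.signal_mean
        y_noiseless = X @ beta + intercept
    else:
        # random position weights on the leading per-residue chemical axis
        raw = np.zeros(X.shape[1])
        raw[np.arange(spec.L_max) * spec.d] = rng.standard_normal(spec.L_max)
        signal = X @ raw
        sd = signal.std()
        if sd == 0:
            raise ValueError("degenerate features: zero signal variance")
        beta = raw * (spec.signal_sd / sd)
        intercept = spec.signal_mean - float(signal.mean()) * (spec.signal_sd / sd)
        y_noiseless = X @ beta + intercept

    if spec.noise_sd is not None:
        noise_sd = spec.noise_sd
    else:
        # sigma such that var(signal) / (var(signal) + sigma^2) = target_r2
        noise_sd = float(y_noiseless.std() * np.sqrt(1.0 / spec.target_r2 - 1.0))
    y = y_noiseless + rng.normal(0.0, noise_sd, size=spec.n_records)
    ic50 = np.power(10.0, y)
    clamped = (ic50 < IC50_MIN_NM) | (ic50 > IC50_MAX_NM)
    ic50 = np.clip(ic50, IC50_MIN_NM, IC50_MAX_NM)
    var_y = float(np.var(y))
    realized_r2 = 1.0 - noise_sd**2 / var_y if var_y > 0 else 1.0

    rows: list[tuple[dict[str, str], int]] = []  # (row, truth index or -1)
    for i, (pep, v) in enumerate(zip(peptides, ic50)):
        rows.append(
            (
                {
                    "Name": render_epitope_name(pep),
                    "Qualitative Measurement": _qualitative_label(v),
                    "Quantitative Measurement": f"{v:.6g}",
                    "Response Measured": spec.response_measured,
                    "HLA": spec.hla_allele,
                    "Epitope IRI": "",
                },
                i,
            )
        )

    # distractors: a fresh valid variant with exactly one corrupted field
    def distractor_row(mode: str) -> dict[str, str]:
        scaffold = scaffolds[rng.integers(0, spec.n_scaffolds)]
        m = 0 if mode == "no_ncaa" else int(
            _sample_from_weights(rng, spec.mods_per_peptide, 1)[0]
        )
        pep = _sample_variant(rng, scaffold, m, ncaa_tokens)
        v = float(rng.uniform(1.0, 10000.0))
        row = {
            "Name": render_epitope_name(pep),
            "Qualitative Measurement": _qualitative_label(v),
            "Quantitative Measurement": f"{v:.6g}",
            "Response Measured": spec.response_measured,
            "HLA": spec.hla_allele,
            "Epitope IRI": "",
        }
        if mode == "missing_quantitative":
            row["Quantitative Measurement"] = ""
        elif mode == "wrong_hla":
            row["HLA"] = "HLA-B*07:02"
        elif mode == "wrong_response":
            row["Response Measured"] = "half maximal effective concentration (EC50)"
        elif mode != "no_ncaa":
            raise ValueError(f"unknown distractor mode {mode!r}")
        return row

    for mode in ("no_ncaa", "missing_quantitative", "wrong_hla", "wrong_response"):
        for _ in range(spec.distractors.get(mode, 0)):
            rows.append((distractor_row(mode), -1))

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    truth_order = [i for _, i in rows if i >= 0]

    truth = GroundTruth(
        coefficients=beta,
        intercept=intercept,
        noise_sd=noise_sd,
        y_noiseless=y_noiseless[truth_order],
        y=y[truth_order],
        realized_r2=realized_r2,
        n_clamped=int(clamped.sum()),
        seed=spec.seed,
    )
    out_rows = [r for r, _ in rows]
    if out_path is not None:
        with open(out_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=EXPORT_COLUMNS, lineterminator="\n"
            )
            writer.writeheader()
            writer.writerows(out_rows)
    return out_rows, truth
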