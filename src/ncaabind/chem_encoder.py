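"""Chemical encoding of residue tokens.

Each residue token (a canonical letter or ``letter-CODE`` NCAA) maps to a
SMILES structure for the free amino acid.  A fixed, packaged list of 208
two-dimensional physicochemical descriptors is evaluated per token; a PCA
fitted on the standardized descriptor matrix of the unique tokens reduces
each descriptor vector to ``d`` (default 10) components; a peptide is then
encoded as the N-to-C concatenation of its residues' reduced vectors,
right-padded with zeros to ``L_max * d`` (default 100) entries, so 9-mers
receive ten trailing zeros and 10-mers none.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit import RDLogger
from sklearn.decomposition import PCA

from .notation import TOKEN_RE, is_ncaa_token

__all__ = [
    "DESCRIPTOR_NAMES",
    "N_DESCRIPTORS",
    "TokenRegistry",
    "ReducerModel",
    "default_registry",
    "load_registry",
    "compute_descriptors",
    "descriptor_matrix",
    "fit_reducer",
    "build_token_map",
    "encode_peptide",
    "encode_dataset",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")


def _load_descriptor_names() -> tuple[str, ...]:
    text = resources.files("ncaabind.data").joinpath("descriptor_names.txt").read_text()
    names = tuple(line.strip() for line in text.splitlines() if line.strip())
    available = {n for n, _ in Descriptors.descList}
    missing = [n for n in names if n not in available]
    if missing:
        raise RuntimeError(f"pinned descriptors not computable by RDKit: {missing}")
    return names


#: pinned descriptor names, fixed order; length defines the raw feature count
DESCRIPTOR_NAMES: tuple[str, ...] = _load_descriptor_names()
N_DESCRIPTORS: int = len(DESCRIPTOR_NAMES)

_DESCRIPTOR_FNS = dict(Descriptors.descList)


class RegistryError(ValueError):
    """Raised for malformed token-registry files."""


@dataclass(frozen=True)
class TokenRegistry:
    """Map from residue-token name to a SMILES structure string."""

    entries: dict[str, str]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        missing = sorted(set("ACDEFGHIKLMNPQRSTVWY") - set(self.entries))
        if missing:
            raise RegistryError(f"registry lacks canonical residues {missing}")
        for token, smiles in self.entries.items():
            if not TOKEN_RE.match(token):
                raise RegistryError(f"invalid token name {token!r}")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise RegistryError(f"unparseable SMILES for token {token!r}: {smiles!r}")
            if mol.GetNumHeavyAtoms() < 4:
                raise RegistryError(
                    f"SMILES for token {token!r} has fewer than 4 heavy atoms"
                )

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def tokens(self) -> list[str]:
        """Token names in a stable order: canonicals alphabetically, then NCAAs."""
        canon = sorted(t for t in self.entries if not is_ncaa_token(t))
        ncaa = sorted(t for t in self.entries if is_ncaa_token(t))
        return canon + ncaa

    def content_hash(self) -> str:
        payload = json.dumps(sorted(self.entries.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def write(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["token", "smiles", "source"])
            for token in self.tokens:
                writer.writerow(
                    [token, self.entries[token], self.provenance.get(token, "")]
                )


def _read_registry_rows(path) -> tuple[dict[str, str], dict[str, str]]:
    entries: dict[str, str] = {}
    provenance: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return entries, provenance
        if "token" not in reader.fieldnames or "smiles" not in reader.fieldnames:
            raise RegistryError(
                f"{path}: registry needs 'token' and 'smiles' columns, "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            token = (row.get("token") or "").strip()
            if not token:
                continue
            if token in entries:
                raise RegistryError(f"{path}: duplicate token {token!r}")
            entries[token] = (row.get("smiles") or "").strip()
            src = (row.get("source") or "").strip()
            if src:
                provenance[token] = src
    return entries, provenance


def _packaged_rows(filename: str) -> tuple[dict[str, str], dict[str, str]]:
    ref = resources.files("ncaabind.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return _read_registry_rows(path)


def default_registry(include_ncaa_pool: bool = True) -> TokenRegistry:
    """The packaged registry: canonical 20, plus the curated NCAA starter set."""
    entries, prov = _packaged_rows("canonical20.tsv")
    if include_ncaa_pool:
        e2, p2 = _packaged_rows("ncaa_pool.tsv")
        entries.update(e2)
        prov.update(p2)
    return TokenRegistry(entries, prov)


def load_registry(path=None) -> TokenRegistry:
    """Load a user registry file, merged over the packaged canonical-20 defaults.

    The file is tab-delimited with columns ``token``, ``smiles`` and optional
    ``source``.  User entries override packaged ones; canonical-20
    completeness is guaranteed by the merge.  ``path=None`` (or an empty
    file) returns the canonical-only default.
    """
    entries, prov = _packaged_rows("canonical20.tsv")
    if path is not None:
        user_entries, user_prov = _read_registry_rows(path)
        entries.update(user_entries)
        prov.update(user_prov)
    return TokenRegistry(entries, prov)


_DESC_CACHE: dict[str, np.ndarray] = {}


def compute_descriptors(smiles: str) -> np.ndarray:
    """Evaluate the pinned descriptor list on one SMILES, fixed order.

    Non-finite descriptor values are imputed to 0 with a warning.  Results
    are cached per SMILES string (descriptor evaluation is pure).
    """
    cached = _DESC_CACHE.get(smiles)
    if cached is not None:
        return cached.copy()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    values = np.empty(N_DESCRIPTORS, dtype=float)
    for i, name in enumerate(DESCRIPTOR_NAMES):
        try:
            values[i] = _DESCRIPTOR_FNS[name](mol)
        except Exception:  # a descriptor failing on an exotic structure
            values[i] = np.nan
    bad = ~np.isfinite(values)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-finite descriptor value(s) for {smiles!r} "
            f"imputed to 0: {[DESCRIPTOR_NAMES[i] for i in np.flatnonzero(bad)[:5]]}",
            stacklevel=2,
        )
        values[bad] = 0.0
    _DESC_CACHE[smiles] = values.copy()
    return values


def descriptor_matrix(registry: TokenRegistry, tokens: list[str] | None = None) -> np.ndarray:
    """Stack descriptor vectors for the given tokens (default: all registry tokens)."""
    tokens = registry.tokens if tokens is None else tokens
    return np.vstack([compute_descriptors(registry.entries[t]) for t in tokens])


@dataclass(frozen=True)
class ReducerModel:
    """Fitted standardize-then-PCA reduction of descriptor space.

    ``transform`` maps a raw descriptor vector x to
    ``((x - mean) / scale) @ loadings`` — a ``d``-vector.
    """

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # p x d, orthonormal columns, sign-fixed
    explained_variance_ratio: np.ndarray
    d: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"expected {self.mean.size} descriptors, got {X.shape[1]}"
            )
        return ((X - self.mean) / self.scale) @ self.loadings

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "d": self.d,
            "descriptor_names": list(DESCRIPTOR_NAMES),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ReducerModel":
        if tuple(payload.get("descriptor_names", DESCRIPTOR_NAMES)) != DESCRIPTOR_NAMES:
            raise ValueError("descriptor-name list mismatch with the packaged order")
        return cls(
            mean=np.asarray(payload["mean"], dtype=float),
            scale=np.asarray(payload["scale"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(
                payload["explained_variance_ratio"], dtype=float
            ),
            d=int(payload["d"]),
        )


def fit_reducer(
    token_descriptor_matrix: np.ndarray, d: int = 10, standardize: bool = True
) -> ReducerModel:
    """Fit the PCA reduction on a unique-token descriptor matrix.

    By default descriptors are z-scored (zero-variance columns get scale 1)
    before the decomposition, so every descriptor is weighted equally:
    descriptor magnitudes span many orders (molecular weight and graph
    information indices versus fragment counts), and unscaled PCA collapses
    onto a single size/complexity axis — ten unscaled components cover
    >99% of raw variance while discarding most of the chemistry.
    ``standardize=False`` gives that raw-variance behaviour when wanted.
    Loading columns are sign-fixed so that each column's largest-magnitude
    element is positive, making the fit reproducible.
    """
    X = np.asarray(token_descriptor_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptor matrix must be 2-D")
    n = X.shape[0]
    if n < d:
        raise ValueError(
            f"{n} token rows cannot support d={d} components; use a smaller d"
        )
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()  # p x d
    # sign convention: largest-|.| element of each column positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
    return ReducerModel(
        mean=mean,
        scale=scale,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        d=d,
    )


def build_token_map(registry: TokenRegistry, reducer: ReducerModel) -> dict[str, np.ndarray]:
    """Map every registry token to its reduced descriptor vector."""
    tokens = registry.tokens
    reduced = reducer.transform(descriptor_matrix(registry, tokens))
    return {t: reduced[i] for i, t in enumerate(tokens)}


def encode_peptide(
    tokens: list[str],
    token_map: dict[str, np.ndarray],
    L_max: int = 10,
    d: int = 10,
) -> np.ndarray:
    """Concatenate per-residue reduced vectors N→C and right-pad with zeros to ``L_max*d``."""
    if not 1 <= len(tokens) <= L_max:
        raise ValueError(
            f"peptide has {len(tokens)} residues; supported range is 1..{L_max}"
        )
    unknown = [t for t in tokens if t not in token_map]
    if unknown:
        raise KeyError(
            f"unregistered token(s) {unknown}; add them to the token registry "
            "(tab-delimited: token, smiles, source)"
        )
    out = np.zeros(L_max * d, dtype=float)
    for i, t in enumerate(tokens):
        vec = np.asarray(token_map[t], dtype=float)
        if vec.size != d:
            raise ValueError(f"token {t!r} mapped to length {vec.size}, expected {d}")
        out[i * d : (i + 1) * d] = vec
    return out


def encode_dataset(
    dataset,
    registry: TokenRegistry,
    d: int = 10,
    L_max: int = 10,
    reducer: ReducerModel | None = None,
    fit_on_dataset_tokens: bool = True,
):
    """Encode a filtered :class:`~ncaabind.iedb_io.AffinityDataset` into a feature matrix.

    Returns ``(X, y, reducer, token_map)`` with ``X`` of shape
    ``(n, L_max*d)`` aligned with dataset order.  By default the reducer is
    fitted on the unique tokens occurring in the dataset plus the canonical
    20, each token once; ``fit_on_dataset_tokens=False`` fits it on every
    registry token instead.
    """
    from .notation import tokenize  # local import to avoid cycle at module load

    token_lists = []
    for idx, pep in enumerate(dataset.peptides):
        toks = tokenize(pep)
        missing = [t for t in toks if t not in registry]
        if missing:
            raise KeyError(
                f"record {idx} ({pep.base_sequence!r}): unregistered token(s) {missing}"
            )
        token_lists.append(toks)

    if reducer is None:
        if fit_on_dataset_tokens:
            fit_tokens = sorted(
                set(t for toks in token_lists for t in toks)
                | set("ACDEFGHIKLMNPQRSTVWY")
            )
        else:
            fit_tokens = registry.tokens
        reducer = fit_reducer(descriptor_matrix(registry, fit_tokens), d=d)
    token_map = build_token_map(registry, reducer)
    X = np.vstack(
        [encode_peptide(toks, token_map, L_max=L_max, d=d) for toks in token_lists]
    )
    y = np.asarray(dataset.targets, dtype=float)
    return X, y, reducer, token_map


def save_encoder(path, reducer: ReducerModel, token_map: dict[str, np.ndarray],
                 registry: TokenRegistry) -> None:
    """Persist reducer + token map as a structured JSON document."""
    payload = {
        "reducer": reducer.to_dict(),
        "token_map": {t: v.tolist() for t, v in token_map.items()},
        "registry_hash": registry.content_hash(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_encoder(path) -> tuple[ReducerModel, dict[str, np.ndarray], str]:
    with open(path) as fh:
        payload = json.load(fh)
    reducer = ReducerModel.from_dict(payload["reducer"])
    token_map = {t: np.asarray(v, dtype=float) for t, v in payload["token_map"].items()}
    return reducer, token_map, payload.get("registry_hash", "")
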