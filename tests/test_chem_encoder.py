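"""Descriptor computation, PCA reduction, token maps and peptide encoding."""

import numpy as np
import pytest

from ncaabind.chem_encoder import (
    DESCRIPTOR_NAMES,
    N_DESCRIPTORS,
    RegistryError,
    build_token_map,
    compute_descriptors,
    default_registry,
    descriptor_matrix,
    encode_dataset,
    encode_peptide,
    fit_reducer,
    load_encoder,
    load_registry,
    save_encoder,
)
from ncaabind.iedb_io import AffinityDataset, AffinityRecord


def standardized_pca_oracle(X, d):
    """Brute-force eigendecomposition of the z-scored covariance matrix."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale
    C = Z.T @ Z / (len(Z) - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    evr = w / w.sum()
    return V[:, :d], evr[:d]


def sign_fix(L):
    L = L.copy()
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] *= -1
    return L


# -- descriptors -------------------------------------------------------- #

def test_descriptor_vector_has_pinned_length():
    vec = compute_descriptors("NCC(=O)O")  # glycine
    assert vec.shape == (208,)
    assert N_DESCRIPTORS == len(DESCRIPTOR_NAMES) == 208
    assert np.all(np.isfinite(vec))


def test_glycine_molecular_weight():
    vec = compute_descriptors("NCC(=O)O")
    mw = vec[DESCRIPTOR_NAMES.index("MolWt")]
    assert mw == pytest.approx(75.07, abs=0.01)  # C2H5NO2


def test_invalid_smiles_rejected():
    with pytest.raises(ValueError, match="unparseable SMILES"):
        compute_descriptors("XYZ")
    with pytest.raises(ValueError):
        compute_descriptors("C(")


# -- registry ----------------------------------------------------------- #

def test_default_registry_contents():
    canon = load_registry(None)
    assert len(canon) == 20
    full = default_registry()
    assert len(full) > 40
    assert "S-PHOS" in full


def test_registry_merge_and_errors(tmp_path):
    path = tmp_path / "reg.tsv"
    path.write_text("token\tsmiles\tsource\nS-PHOS\tN[C@@H](COP(=O)(O)O)C(=O)O\tphosphoserine\n")
    reg = load_registry(path)
    assert len(reg) == 21 and "S-PHOS" in reg

    (tmp_path / "empty.tsv").write_text("token\tsmiles\n")
    assert len(load_registry(tmp_path / "empty.tsv")) == 20

    (tmp_path / "bad.tsv").write_text("token\tsmiles\nS-PHOS\tC(\n")
    with pytest.raises(RegistryError, match="S-PHOS"):
        load_registry(tmp_path / "bad.tsv")

    (tmp_path / "dup.tsv").write_text(
        "token\tsmiles\nK-ME1\tCNCCCC[C@H](N)C(=O)O\nK-ME1\tCNCCCC[C@H](N)C(=O)O\n"
    )
    with pytest.raises(RegistryError, match="duplicate"):
        load_registry(tmp_path / "dup.tsv")


def test_registry_write_read_round_trip(tmp_path, small_registry):
    path = tmp_path / "reg.tsv"
    small_registry.write(path)
    reloaded = load_registry(path)
    assert reloaded.entries == small_registry.entries


# -- reducer ------------------------------------------------------------ #

def test_reducer_rank_one_input(rng):
    direction = rng.standard_normal(208)
    X = np.outer(rng.standard_normal(30), direction) + rng.standard_normal(208)
    red = fit_reducer(X, d=5)
    assert red.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)


def test_reducer_matches_eigendecomposition_oracle(rng):
    X = rng.standard_normal((30, 12))
    red = fit_reducer(X, d=6, standardize=True)
    V, evr = standardized_pca_oracle(X, 6)
    assert np.allclose(red.explained_variance_ratio, evr, atol=1e-8)
    assert np.allclose(red.loadings, sign_fix(V), atol=1e-8)
    # loading columns orthonormal
    G = red.loadings.T @ red.loadings
    assert np.allclose(G, np.eye(6), atol=1e-8)
    assert red.explained_variance_ratio.sum() <= 1 + 1e-8
    assert np.all(np.diff(red.explained_variance_ratio) <= 1e-12)


def test_reducer_unscaled_matches_raw_covariance_oracle(rng):
    X = rng.standard_normal((30, 12)) * np.logspace(0, 3, 12)
    red = fit_reducer(X, d=4, standardize=False)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / 29
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    assert np.allclose(red.explained_variance_ratio, (w / w.sum())[order][:4], atol=1e-8)
    assert np.allclose(red.loadings, sign_fix(V[:, order][:, :4]), atol=1e-8)


def test_reducer_too_few_rows():
    with pytest.raises(ValueError, match="smaller d"):
        fit_reducer(np.zeros((5, 208)), d=10)


def test_reducer_transform_of_mean_is_zero(rng):
    X = rng.standard_normal((25, 15))
    red = fit_reducer(X, d=3)
    assert np.allclose(red.transform(X.mean(axis=0)), 0.0, atol=1e-10)


# -- token map & encoding ----------------------------------------------- #

def test_token_map_domain_and_dimensions(small_registry):
    red = fit_reducer(descriptor_matrix(small_registry), d=10)
    tmap = build_token_map(small_registry, red)
    assert set(tmap) == set(small_registry.entries)
    assert all(v.shape == (10,) for v in tmap.values())


def test_encode_peptide_padding():
    d = 10
    tmap = {t: np.full(d, i + 1.0) for i, t in enumerate("ACDEFGHIKL")}
    nine = encode_peptide(list("ACDEFGHIK"), tmap, L_max=10, d=d)
    assert nine.shape == (100,)
    assert np.all(nine[90:] == 0.0)
    assert np.all(nine[:90] != 0.0)
    ten = encode_peptide(list("ACDEFGHIKL"), tmap, L_max=10, d=d)
    assert ten.shape == (100,)
    assert np.all(ten != 0.0)
    # padding invariant: strip trailing zeros and re-pad
    stripped = nine[:90]
    repad = np.concatenate([stripped, np.zeros(10)])
    assert np.array_equal(repad, nine)


def test_encode_peptide_errors():
    tmap = {"A": np.zeros(10)}
    with pytest.raises(KeyError, match="K-FOO"):
        encode_peptide(["A", "K-FOO"], tmap)
    with pytest.raises(ValueError, match="1..10"):
        encode_peptide(["A"] * 11, tmap)


def test_encode_dataset_shapes_and_determinism(small_registry):
    ds = AffinityDataset([
        AffinityRecord(name="ACDEFGHIK", quantitative=10.0),
        AffinityRecord(name="ACDEFGHIKL", quantitative=100.0),
    ])
    X1, y1, red, tmap = encode_dataset(ds, small_registry)
    X2, y2, _, _ = encode_dataset(ds, small_registry)
    assert X1.shape == (2, 100)
    assert np.all(X1[0, 90:] == 0.0)       # 9-mer row ends in ten zeros
    assert not np.all(X1[1, 90:] == 0.0)   # 10-mer row has no padding
    assert np.array_equal(X1, X2) and np.array_equal(y1, y2)
    assert np.allclose(y1, [1.0, 2.0])


def test_encode_dataset_unregistered_token(small_registry):
    ds = AffinityDataset([
        AffinityRecord(name="ACDEFGHIK + ZZZZ(K9)", quantitative=10.0),
    ])
    with pytest.raises(KeyError, match="K-ZZZZ"):
        encode_dataset(ds, small_registry)


def test_encoder_persistence_round_trip(tmp_path, small_registry):
    red = fit_reducer(descriptor_matrix(small_registry), d=10)
    tmap = build_token_map(small_registry, red)
    path = tmp_path / "encoder.json"
    save_encoder(path, red, tmap, small_registry)
    red2, tmap2, reg_hash = load_encoder(path)
    assert reg_hash == small_registry.content_hash()
    assert np.allclose(red.loadings, red2.loadings)
    for t in tmap:
        assert np.allclose(tmap[t], tmap2[t])
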