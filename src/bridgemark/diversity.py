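"""Band-score genotype matrices, allele statistics (gene diversity, PIC),
classical Fst over species groups, Nei genetic distances, and neighbor-joining
trees.

Accessions are treated as homozygous inbred lines: exactly one band present
per locus (or the locus missing for that accession). Gene diversity is the
expected heterozygosity D = 1 - sum(p_i^2); PIC follows Botstein's formula
PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2. "Nei's distance" defaults to
Nei's minimum genetic distance D_m = mean over loci of (J_X + J_Y)/2 - J_XY,
with the 1972 standard distance and the D_A distance available as
alternatives.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import skbio


class HeterozygousPatternError(ValueError):
    """An accession shows more than one band at a locus."""


class GenotypeMatrix:
    """Accessions x band-allele 0/1 scores with optional species labels.

    Columns are named ``locus:allele``. Per accession and locus either
    exactly one allele is scored 1 (present) or the whole locus is missing
    (all-NaN), matching gel scoring of pure lines.
    """

    def __init__(self, frame: pd.DataFrame, species: pd.Series | None = None):
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in frame.columns], names=["locus", "allele"]
        )
        self.data = frame.copy()
        self.data.columns = cols
        self.species = species.reindex(frame.index) if species is not None else None
        self._validate()

    def _validate(self) -> None:
        for locus in self.loci:
            block = self.data[locus]
            present = block.sum(axis=1, skipna=True)
            missing = block.isna().all(axis=1)
            bad_multi = present[(present > 1) & ~missing]
            if len(bad_multi):
                raise HeterozygousPatternError(
                    f"accession {bad_multi.index[0]!r} shows {int(bad_multi.iloc[0])} "
                    f"bands at locus {locus!r}; expected one band per pure line"
                )
            bad_none = present[(present != 1) & ~missing]
            if len(bad_none):
                raise ValueError(
                    f"accession {bad_none.index[0]!r} has no band at locus {locus!r} "
                    "but is not scored missing"
                )

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("locus")))

    @property
    def n_data_points(self) -> int:
        """Accessions x band alleles (cells of the score matrix)."""
        return self.data.shape[0] * self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.columns = [f"{l}:{a}" for l, a in out.columns]
        if self.species is not None:
            out.insert(0, "species", self.species)
        out.to_csv(path, sep="\t", index_label="accession")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="accession")
        species = None
        if "species" in df.columns:
            species = df.pop("species")
        return cls(df, species=species)


def allele_frequencies(matrix: GenotypeMatrix) -> dict[str, pd.Series]:
    """Per-locus allele frequency vectors over non-missing accessions."""
    freqs: dict[str, pd.Series] = {}
    for locus in matrix.loci:
        block = matrix.data[locus].dropna(how="all")
        if block.empty:
            continue
        counts = block.sum(axis=0)
        p = counts / counts.sum()
        p.attrs["n"] = len(block)
        freqs[locus] = p
    return freqs


def gene_diversity(p: np.ndarray) -> float:
    return float(1.0 - np.sum(np.asarray(p) ** 2))


def pic(p: np.ndarray) -> float:
    """Botstein's polymorphism information content."""
    p = np.asarray(p, dtype=float)
    p2 = p**2
    cross = np.sum(np.outer(p2, p2)) - np.sum(p2**2)  # 2*sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(p2) - cross)


def allele_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus allele count, major allele frequency, gene diversity and PIC.

    Loci with every accession missing are reported as all-NaN rows.
    """
    rows = {}
    freqs = allele_frequencies(matrix)
    for locus in matrix.loci:
        if locus not in freqs:
            rows[locus] = dict.fromkeys(
                ("n_alleles", "maf", "gene_diversity", "pic", "n"), np.nan
            )
            continue
        p = freqs[locus]
        observed = p[p > 0].to_numpy()
        rows[locus] = {
            "n_alleles": int((p > 0).sum()),
            "maf": float(p.max()),
            "gene_diversity": gene_diversity(observed),
            "pic": pic(observed),
            "n": p.attrs["n"],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def fst(matrix: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Classical Fst = (H_T - H_S) / H_T per locus over species groups, with
    H_T from unweighted mean allele frequencies across groups.

    Loci monomorphic across all groups (H_T = 0) are undefined and excluded;
    the mean is the ratio of sums sum(H_T - H_S) / sum(H_T) over defined loci.
    """
    if matrix.species is None:
        raise ValueError("species labels required for Fst")
    groups = matrix.species.dropna().unique()
    if len(groups) < 2:
        raise ValueError("Fst needs at least two species groups")
    per_locus = {}
    num_sum = 0.0
    den_sum = 0.0
    for locus in matrix.loci:
        block = matrix.data[locus]
        group_freqs = []
        for g in groups:
            sub = block.loc[matrix.species == g].dropna(how="all")
            if sub.empty:
                continue
            counts = sub.sum(axis=0)
            group_freqs.append((counts / counts.sum()).to_numpy())
        if len(group_freqs) < 2:
            per_locus[locus] = np.nan
            continue
        pbar = np.mean(group_freqs, axis=0)
        h_t = 1.0 - np.sum(pbar**2)
        h_s = float(np.mean([1.0 - np.sum(p**2) for p in group_freqs]))
        if h_t <= 0:
            per_locus[locus] = np.nan
            continue
        per_locus[locus] = (h_t - h_s) / h_t
        num_sum += h_t - h_s
        den_sum += h_t
    mean_fst = num_sum / den_sum if den_sum > 0 else float("nan")
    return pd.Series(per_locus, name="fst"), mean_fst


# ---------------------------------------------------------------------------
# genetic distances


def _aligned(freqs_x: Mapping[str, pd.Series], freqs_y: Mapping[str, pd.Series]):
    if set(freqs_x) != set(freqs_y):
        raise ValueError("locus sets differ between the two frequency profiles")
    for locus in sorted(freqs_x):
        x, y = freqs_x[locus], freqs_y[locus]
        alleles = x.index.union(y.index)
        yield x.reindex(alleles, fill_value=0.0).to_numpy(), y.reindex(
            alleles, fill_value=0.0
        ).to_numpy()


def nei_distance(
    freqs_x: Mapping[str, pd.Series], freqs_y: Mapping[str, pd.Series]
) -> float:
    """Nei's minimum genetic distance: mean over loci of (J_X+J_Y)/2 - J_XY."""
    terms = [
        (np.sum(x**2) + np.sum(y**2)) / 2 - np.sum(x * y)
        for x, y in _aligned(freqs_x, freqs_y)
    ]
    return float(np.mean(terms))


def nei_standard_distance(
    freqs_x: Mapping[str, pd.Series], freqs_y: Mapping[str, pd.Series]
) -> float:
    """Nei's 1972 standard distance D = -ln(J_XY / sqrt(J_X J_Y)), with the
    identity sums accumulated over loci."""
    jx = jy = jxy = 0.0
    for x, y in _aligned(freqs_x, freqs_y):
        jx += float(np.sum(x**2))
        jy += float(np.sum(y**2))
        jxy += float(np.sum(x * y))
    if jxy <= 0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_da_distance(
    freqs_x: Mapping[str, pd.Series], freqs_y: Mapping[str, pd.Series]
) -> float:
    """Nei's D_A distance 1 - mean over loci of sum(sqrt(x_i y_i))."""
    terms = [np.sum(np.sqrt(x * y)) for x, y in _aligned(freqs_x, freqs_y)]
    return float(1.0 - np.mean(terms))


_DISTANCES: dict[str, Callable] = {
    "nei_minimum": nei_distance,
    "nei_standard": nei_standard_distance,
    "nei_da": nei_da_distance,
}


def distance_matrix(
    matrix: GenotypeMatrix,
    level: str = "accession",
    method: str = "nei_minimum",
) -> pd.DataFrame:
    """Symmetric distance matrix between accessions or species groups."""
    dist_fn = _DISTANCES[method]
    profiles: dict[str, dict[str, pd.Series]] = {}
    if level == "accession":
        for acc in matrix.accessions:
            prof = {}
            for locus in matrix.loci:
                row = matrix.data.loc[acc, locus]
                if row.isna().all():
                    continue
                prof[locus] = row.astype(float)
            profiles[acc] = prof
    elif level == "species":
        if matrix.species is None:
            raise ValueError("species labels required")
        for g in matrix.species.dropna().unique():
            sub = GenotypeMatrix(
                matrix.data.loc[matrix.species == g].pipe(_flatten_columns)
            )
            profiles[g] = allele_frequencies(sub)
    else:
        raise ValueError(f"unknown level {level!r}")
    labels = list(profiles)
    # complete-case per pair: restrict to loci typed in both profiles
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(profiles[labels[i]]) & set(profiles[labels[j]])
            if not shared:
                raise ValueError(
                    f"no shared typed loci between {labels[i]} and {labels[j]}"
                )
            xi = {l: profiles[labels[i]][l] for l in shared}
            yj = {l: profiles[labels[j]][l] for l in shared}
            out[i, j] = out[j, i] = dist_fn(xi, yj)
    return pd.DataFrame(out, index=labels, columns=labels)


def _flatten_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out.columns = [f"{l}:{a}" for l, a in df.columns]
    return out


def write_phylip(path: str | Path, dist: pd.DataFrame) -> None:
    """Distance matrix in relaxed PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist)}\n")
        for label in dist.index:
            row = " ".join(f"{v:.6f}" for v in dist.loc[label])
            fh.write(f"{label} {row}\n")


# ---------------------------------------------------------------------------
# neighbor joining


@dataclasses.dataclass
class PhyloTree:
    newick: str

    def skbio_tree(self) -> skbio.TreeNode:
        return skbio.TreeNode.read(io.StringIO(self.newick))


class _Node:
    __slots__ = ("newick", "rep")

    def __init__(self, newick: str, rep: str):
        self.newick = newick  # newick fragment without trailing length
        self.rep = rep  # lexicographically smallest leaf beneath (tie-break key)


def nj_tree(dist: pd.DataFrame, clamp_negative: bool = True) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Deterministic: ties in Q resolve to the lexicographically smallest pair
    of (smallest-leaf) labels. Negative branch lengths are clamped to zero
    with the excess moved to the sibling edge unless ``clamp_negative`` is
    False. Exact on additive matrices. Returns an unrooted tree whose root
    node is the final trifurcation.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dist.to_numpy(dtype=float).copy()
    if list(dist.columns) != labels:
        raise ValueError("distance matrix index and columns differ")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    nodes = [_Node(str(l), str(l)) for l in labels]

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((nodes[i].rep, nodes[j].rep)))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and key < best[2]
                ):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
            li, lj = max(li, 0.0), max(lj, 0.0)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        merged = _Node(
            f"({nodes[i].newick}:{fmt(li)},{nodes[j].newick}:{fmt(lj)})",
            min(nodes[i].rep, nodes[j].rep),
        )
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [merged]

    # resolve the final three nodes with the three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    order = sorted(range(3), key=lambda k: nodes[k].rep)
    parts = [(a.newick, la), (b.newick, lb), (c.newick, lc)]
    newick = "(" + ",".join(f"{parts[k][0]}:{fmt(parts[k][1])}" for k in order) + ");"
    return PhyloTree(newick)


def species_cluster_purity(tree: PhyloTree, species: Mapping[str, str]) -> float:
    """Fraction of species whose accessions form a connected leaf cluster
    (the subtree spanning them contains no other species' leaves)."""
    t = tree.skbio_tree()
    adj: dict[int, set[int]] = {}
    leaf_of: dict[str, int] = {}
    ids: dict[int, object] = {}

    def nid(node) -> int:
        return id(node)

    for node in t.traverse(include_self=True):
        ids[nid(node)] = node
        adj.setdefault(nid(node), set())
        for child in node.children:
            adj[nid(node)].add(nid(child))
            adj.setdefault(nid(child), set()).add(nid(node))
        if node.is_tip():
            leaf_of[node.name] = nid(node)

    def steiner_nodes(leaves: list[int]) -> set[int]:
        # union of paths between the leaves: iteratively prune degree-1
        # nodes that are not target leaves
        keep = set(adj)
        deg = {k: len(v) for k, v in adj.items()}
        targets = set(leaves)
        changed = True
        while changed:
            changed = False
            for k in list(keep):
                if k not in targets and deg[k] <= 1:
                    keep.discard(k)
                    for nb in adj[k]:
                        if nb in keep:
                            deg[nb] -= 1
                    deg[k] = 0
                    changed = True
        return keep

    by_species: dict[str, list[str]] = {}
    for acc, sp in species.items():
        by_species.setdefault(sp, []).append(acc)
    pure = 0
    for sp, accs in by_species.items():
        sub = steiner_nodes([leaf_of[a] for a in accs])
        foreign = [
            name for name, lid in leaf_of.items() if lid in sub and species[name] != sp
        ]
        if not foreign:
            pure += 1
    return pure / len(by_species)
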