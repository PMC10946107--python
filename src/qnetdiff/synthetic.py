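"""Synthetic paired count tables with planted network structure.

The generator emulates the statistical features the rewiring method relies
on, so the whole pipeline is testable without any sequencing data:

* compositional counts — multinomial draws at a random sequencing depth from
  log-normal latent (basis) abundances;
* a multi-mapping artefact — one latent taxon's counts split multinomially
  among *k* sibling genera that share a parent-level category, giving the
  near-identical count rows that cause false correlations;
* planted differential taxa — a fold-change increase of the latent abundance
  in group Y.  Each purely differential taxon is also given two stably
  correlated partner taxa (same partners in both groups) so it keeps at
  least one network edge and survives joint-isolate pruning;
* a planted rewiring taxon — its latent log-abundance shares a common factor
  with partner set S in group X but with a disjoint set T in group Y
  (within-group log correlation ``rewiring_corr``), so its co-occurrence
  partners switch between groups.  It is itself differential so that it
  enters the core set and hence the scored subnetwork.

Ground truth records every planted label for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import CountTable, Taxonomy

__all__ = ["FixtureSpec", "GroundTruth", "generate_fixture", "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic two-group experiment."""

    n_taxa: int = 40
    n_samples: int = 60  # per group
    seed: int = 0
    depth_range: tuple[int, int] = (20_000, 50_000)
    sibling_set_sizes: tuple[int, ...] = (3,)
    n_differential: int = 2  # purely differential taxa (rewiring taxon extra)
    fold_change: float = 4.0
    n_rewiring_partners: int = 4  # |S| = |T|
    rewiring_corr: float = 0.9
    n_stable_partners: int = 2  # per purely differential taxon
    log_mean_sd: float = 1.0  # spread of per-taxon mean log abundance
    log_sd: float = 1.0  # per-sample log-abundance variation


@dataclass
class GroundTruth:
    """Planted labels of a generated fixture."""

    rewiring_taxon: str
    rewiring_partners_x: list[str]
    rewiring_partners_y: list[str]
    differential: list[str]  # all taxa with the fold change (incl. rewiring)
    stable_partners: dict[str, list[str]]
    sibling_sets: list[list[str]]
    sibling_representatives: list[str]  # highest-share member per set

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def _sibling_shares(k: int) -> np.ndarray:
    """Near-equal but distinct multinomial shares, largest first."""
    raw = 1.0 + 0.2 * np.linspace(1.0, -1.0, k)
    return raw / raw.sum()


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[CountTable, CountTable, Taxonomy, GroundTruth]:
    """Draw paired count tables, a taxonomy, and the planted ground truth.

    Identical specs (including seed) produce byte-identical tables.
    """
    n_sib_extra = sum(k - 1 for k in spec.sibling_set_sizes)
    n_latent = spec.n_taxa - n_sib_extra
    n_special = (
        1  # rewiring taxon
        + 2 * spec.n_rewiring_partners
        + spec.n_differential * (1 + spec.n_stable_partners)
        + len(spec.sibling_set_sizes)
    )
    if any(k < 2 for k in spec.sibling_set_sizes):
        raise ValueError("sibling sets need k >= 2")
    if n_latent < n_special:
        raise ValueError(
            f"infeasible spec: {n_special} planted latent taxa exceed the "
            f"{n_latent} latent slots available for n_taxa={spec.n_taxa}"
        )

    rng = np.random.default_rng(spec.seed)

    # ---- latent role layout ------------------------------------------------
    idx = iter(range(n_latent))
    i_rewire = next(idx)
    i_s = [next(idx) for _ in range(spec.n_rewiring_partners)]
    i_t = [next(idx) for _ in range(spec.n_rewiring_partners)]
    i_diff = []
    i_partners: list[list[int]] = []
    for _ in range(spec.n_differential):
        i_diff.append(next(idx))
        i_partners.append([next(idx) for _ in range(spec.n_stable_partners)])
    i_sib_parent = [next(idx) for _ in spec.sibling_set_sizes]

    mu = rng.normal(0.0, spec.log_mean_sd, size=n_latent)
    differential_latent = [i_rewire] + i_diff
    mu_y = mu.copy()
    mu_y[differential_latent] += np.log(spec.fold_change)

    rho = spec.rewiring_corr
    stable_blocks = [[d] + ps for d, ps in zip(i_diff, i_partners)]

    def draw_group(mu_g: np.ndarray, blocks: list[list[int]]) -> np.ndarray:
        """Latent log abundances (n_latent x n_samples) with factor blocks."""
        eps = rng.standard_normal((n_latent, spec.n_samples))
        log_a = mu_g[:, None] + spec.log_sd * eps
        for block in blocks:
            if len(block) < 2:  # a "block" of one taxon plants nothing
                continue
            f = rng.standard_normal(spec.n_samples)
            for i in block:
                log_a[i] = mu_g[i] + spec.log_sd * (
                    np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps[i]
                )
        return log_a

    def draw_counts(log_a: np.ndarray) -> np.ndarray:
        a = np.exp(log_a)
        p = a / a.sum(axis=0)
        depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1,
                              size=spec.n_samples)
        counts = np.empty((n_latent, spec.n_samples), dtype=np.int64)
        for k in range(spec.n_samples):
            counts[:, k] = rng.multinomial(depths[k], p[:, k])
        return counts

    blocks_x = [[i_rewire] + i_s] + stable_blocks
    blocks_y = [[i_rewire] + i_t] + stable_blocks
    counts_x = draw_counts(draw_group(mu, blocks_x))
    counts_y = draw_counts(draw_group(mu_y, blocks_y))

    # ---- expand sibling parents into observed sibling genera ---------------
    name = [f"g{i:03d}" for i in range(spec.n_taxa)]
    obs_of_latent: dict[int, int] = {}
    sib_members: list[list[int]] = []  # observed indices per sibling set
    next_obs = 0
    parent_set = {p: s for s, p in enumerate(i_sib_parent)}
    for i in range(n_latent):
        if i in parent_set:
            k = spec.sibling_set_sizes[parent_set[i]]
            sib_members.append(list(range(next_obs, next_obs + k)))
            next_obs += k
        else:
            obs_of_latent[i] = next_obs
            next_obs += 1
    assert next_obs == spec.n_taxa

    def split_siblings(counts: np.ndarray) -> np.ndarray:
        obs = np.zeros((spec.n_taxa, spec.n_samples), dtype=np.int64)
        for i in range(n_latent):
            if i in parent_set:
                members = sib_members[parent_set[i]]
                shares = _sibling_shares(len(members))
                for k in range(spec.n_samples):
                    obs[members, k] = rng.multinomial(counts[i, k], shares)
            else:
                obs[obs_of_latent[i]] = counts[i]
        return obs

    obs_x = split_siblings(counts_x)
    obs_y = split_siblings(counts_y)

    samples_x = [f"X{k:03d}" for k in range(spec.n_samples)]
    samples_y = [f"Y{k:03d}" for k in range(spec.n_samples)]
    ct_x = CountTable("X", pd.DataFrame(obs_x, index=name, columns=samples_x))
    ct_y = CountTable("Y", pd.DataFrame(obs_y, index=name, columns=samples_y))

    # ---- taxonomy: siblings share a family, everything else is unique ------
    mapping = {t: f"fam_{t}" for t in name}
    for s, members in enumerate(sib_members):
        for m in members:
            mapping[name[m]] = f"fam_sib{s:02d}"
    taxonomy = Taxonomy(mapping)

    truth = GroundTruth(
        rewiring_taxon=name[obs_of_latent[i_rewire]],
        rewiring_partners_x=[name[obs_of_latent[i]] for i in i_s],
        rewiring_partners_y=[name[obs_of_latent[i]] for i in i_t],
        differential=[name[obs_of_latent[i]] for i in differential_latent],
        stable_partners={
            name[obs_of_latent[d]]: [name[obs_of_latent[p]] for p in ps]
            for d, ps in zip(i_diff, i_partners)
        },
        sibling_sets=[[name[m] for m in members] for members in sib_members],
        sibling_representatives=[name[members[0]] for members in sib_members],
    )
    return ct_x, ct_y, taxonomy, truth


def write_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Generate a fixture and write its four files into ``out_dir``.

    Returns the paths (counts X, counts Y, taxonomy, ground truth JSON).
    """
    from .tables_io import write_count_table, write_taxonomy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct_x, ct_y, taxonomy, truth = generate_fixture(spec)
    paths = (
        out / "counts_X.tsv",
        out / "counts_Y.tsv",
        out / "taxonomy.tsv",
        out / "ground_truth.json",
    )
    write_count_table(ct_x, paths[0])
    write_count_table(ct_y, paths[1])
    write_taxonomy(taxonomy, paths[2])
    truth.to_json(paths[3])
    return paths
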