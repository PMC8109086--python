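import numpy as np
import pytest

from mrsuite.instruments import (
    LDSourceError,
    TabularLDSource,
    TraitCatalog,
    clump,
    exclude_pleiotropic_traits,
    filter_significant,
)
from mrsuite.simulate import ScenarioConfig, generate

from conftest import make_dataset, make_variant


# --------------------------------------------------------------- significance

def test_filter_keeps_rows_strictly_below_threshold():
    ds = make_dataset([
        make_variant("rs1", pval=1e-9),
        make_variant("rs2", pos=2000, pval=4e-8),
        make_variant("rs3", pos=3000, pval=6e-8),
    ])
    assert filter_significant(ds, 5e-8).rsids == ["rs1", "rs2"]


def test_filter_threshold_one_keeps_all_and_empty_in_empty_out():
    ds = make_dataset([make_variant("rs1", pval=0.99),
                       make_variant("rs2", pos=2000, pval=0.5)])
    assert filter_significant(ds, 1.0).rsids == ["rs1", "rs2"]
    assert len(filter_significant(make_dataset([]), 0.5)) == 0


# ------------------------------------------------------------------- clumping

def test_clump_removes_correlated_neighbour():
    ds = make_dataset([
        make_variant("rsA", pos=1000, pval=1e-10),
        make_variant("rsB", pos=6000, pval=1e-9),
    ])
    ld = TabularLDSource({("rsA", "rsB"): 0.5})
    assert clump(ds, ld, 0.001, 10_000).rsids == ["rsA"]


def test_clump_keeps_sub_threshold_pair():
    ds = make_dataset([
        make_variant("rsA", pos=1000, pval=1e-10),
        make_variant("rsC", pos=6000, pval=1e-9),
    ])
    ld = TabularLDSource({("rsA", "rsC"): 0.0005})
    assert clump(ds, ld, 0.001, 10_000).rsids == ["rsA", "rsC"]


def test_clump_single_record_is_identity():
    ds = make_dataset([make_variant("rsA")])
    assert clump(ds, TabularLDSource()).rsids == ["rsA"]


def test_clump_missing_ld_policy():
    ds = make_dataset([
        make_variant("rsA", pos=1000, pval=1e-10),
        make_variant("rsB", pos=6000, pval=1e-9),
    ])
    empty = TabularLDSource()
    assert clump(ds, empty, missing_ld="remove").rsids == ["rsA"]
    assert clump(ds, empty, missing_ld="keep").rsids == ["rsA", "rsB"]


def test_clump_propagates_ld_failure_naming_pair():
    class Broken:
        def r2(self, a, b):
            raise RuntimeError("panel offline")

    ds = make_dataset([
        make_variant("rsA", pos=1000, pval=1e-10),
        make_variant("rsB", pos=2000, pval=1e-9),
    ])
    with pytest.raises(LDSourceError, match="rsA.*rsB"):
        clump(ds, Broken())


def _random_clump_case(rng, n=25):
    records = [
        make_variant(
            f"rs{i}", chrom=str(rng.integers(1, 3)),
            pos=int(rng.integers(1, 40) * 1000),
            pval=float(rng.uniform(1e-12, 1e-6)),
        )
        for i in range(n)
    ]
    # unique (chrom,pos) not required; rsids unique
    ld = TabularLDSource()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.6:  # leave some pairs unknown
                ld.add(f"rs{i}", f"rs{j}", float(rng.random() * 0.01))
    return make_dataset(records), ld


def _brute_force_clump(dataset, ld, r2_threshold, window_bp):
    """Independent greedy reference: explicit list scan, no shortcuts."""
    pool = sorted(dataset.records,
                  key=lambda r: (r.pval, r.chrom, r.pos, r.rsid))
    kept = []
    while pool:
        idx = pool[0]
        kept.append(idx)
        nxt = []
        for cand in pool[1:]:
            near = (cand.chrom == idx.chrom
                    and abs(cand.pos - idx.pos) <= window_bp)
            if near:
                r2 = ld.r2(idx.rsid, cand.rsid)
                if r2 is None or r2 >= r2_threshold:
                    continue
            nxt.append(cand)
        pool = nxt
    return sorted(r.rsid for r in kept)


@pytest.mark.parametrize("case_seed", range(8))
def test_clump_matches_brute_force_and_postcondition(case_seed):
    rng = np.random.default_rng(case_seed)
    ds, ld = _random_clump_case(rng)
    result = clump(ds, ld, 0.001, 10_000)
    assert sorted(result.rsids) == _brute_force_clump(ds, ld, 0.001, 10_000)
    # postcondition: no retained same-chromosome pair within the window
    # is in LD at or above the threshold (missing treated as correlated)
    for i, a in enumerate(result.records):
        for b in result.records[i + 1:]:
            if a.chrom == b.chrom and abs(a.pos - b.pos) <= 10_000:
                r2 = ld.r2(a.rsid, b.rsid)
                assert r2 is not None and r2 < 0.001


def test_clump_idempotent_and_order_invariant(rng):
    ds, ld = _random_clump_case(rng)
    once = clump(ds, ld)
    assert clump(once, ld).rsids == once.rsids
    perm = make_dataset([ds.records[i]
                         for i in rng.permutation(len(ds.records))])
    assert clump(perm, ld).rsids == once.rsids


def test_clump_recovers_one_snp_per_ld_block():
    study = generate(ScenarioConfig(ld_blocks=(12, 4, 0.6),
                                    true_beta=0.1, palindrome_fraction=0.0,
                                    seed=42))
    clumped = clump(study.exposure, study.ld, 0.001, 10_000)
    assert len(clumped) == 12
    by_block = {}
    for rec in study.exposure.records:
        blk = study.truth.block[study.truth.rsids.index(rec.rsid)]
        by_block.setdefault(blk, []).append(rec)
    for rec in clumped.records:
        blk = study.truth.block[study.truth.rsids.index(rec.rsid)]
        best = min(by_block[blk], key=lambda r: r.pval)
        assert rec.rsid == best.rsid


# --------------------------------------------------------------- trait screen

def _catalog():
    return TraitCatalog(
        associations={
            "rs1": [("body mass index", 1e-9)],
            "rs2": [("body mass index", 1e-6)],
            "rs4": [("height", 1e-20)],
        },
        excluded_traits=["body mass index", "diabetes"],
    )


def test_trait_exclusion_below_threshold_only():
    ds = make_dataset([make_variant("rs1"), make_variant("rs2", pos=2000),
                       make_variant("rs3", pos=3000)])
    kept, log = exclude_pleiotropic_traits(ds, _catalog(), 5e-8)
    assert kept.rsids == ["rs2", "rs3"]  # rs2 above threshold, rs3 absent
    assert log == [("rs1", "body mass index", 1e-9)]


def test_non_excluded_trait_does_not_trigger_removal():
    ds = make_dataset([make_variant("rs4")])
    kept, log = exclude_pleiotropic_traits(ds, _catalog(), 5e-8)
    assert kept.rsids == ["rs4"] and log == []
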