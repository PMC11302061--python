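"""Sample-level orchestration, profiles and the command line."""

import json
import os

import pytest

from pmprofiler.io_formats import SequenceRecord, read_profile
from pmprofiler.kmer_index import build_index
from pmprofiler.profiler import Profile, profile_sample, run_cli
from pmprofiler.simulate_eval import SimConfig, simulate_database, simulate_sample


@pytest.fixture(scope="module")
def planted():
    """A tiny database plus error-free reads planted from one species."""
    import numpy as np

    cfg = SimConfig(
        n_species=6,
        n_sample_species=6,
        n_reads=10,
        within_species_divergence=0.0,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        near_identical_fraction=0.0,
        seed=9,
    )
    rng = np.random.default_rng(9)
    db = simulate_database(cfg, rng=rng)
    index = build_index(db.records, k=15)
    return cfg, db, index


class TestProfileSample:
    def test_planted_reads_recovered(self, planted):
        import numpy as np

        cfg, db, index = planted
        reads, truth = simulate_sample(db, cfg, rng=np.random.default_rng(10))
        profiles, anns = profile_sample(reads, index, db.taxonomy, mode="both")
        hwl = profiles["HWL"]
        assert hwl.n_reads == 10 and hwl.n_annotated == 10
        for lin, count in hwl.counts.items():
            assert count == sum(1 for l in truth.read_to_species.values() if str(l) == lin)

    def test_empty_read_stream(self, planted):
        _, db, index = planted
        profiles, anns = profile_sample([], index, db.taxonomy, mode="both")
        assert profiles["HWL"].n_reads == 0 and profiles["HWL"].counts == {}
        assert anns == []

    def test_both_modes_see_same_reads(self, planted):
        import numpy as np

        cfg, db, index = planted
        reads, _ = simulate_sample(db, cfg, rng=np.random.default_rng(11))
        profiles, _ = profile_sample(reads, index, db.taxonomy, mode="both")
        for p in profiles.values():
            assert p.n_annotated + p.n_unclassified == p.n_reads == len(reads)

    def test_unclassified_read_counted(self, planted):
        _, db, index = planted
        junk = SequenceRecord("junk", "ACGT" * 80)
        profiles, anns = profile_sample([junk], index, db.taxonomy, mode="hwl")
        assert profiles["HWL"].n_unclassified == 1
        assert anns[0].is_classified is False

    def test_worker_count_invariance(self, planted):
        import numpy as np

        cfg, db, index = planted
        reads, _ = simulate_sample(db, cfg, rng=np.random.default_rng(12))
        p1, a1 = profile_sample(reads, index, db.taxonomy, n_workers=1)
        p4, a4 = profile_sample(reads, index, db.taxonomy, n_workers=4)
        assert {s: p.counts for s, p in p1.items()} == {s: p.counts for s, p in p4.items()}
        assert [(a.read_id, a.strategy, str(a.lineage)) for a in a1] == [
            (a.read_id, a.strategy, str(a.lineage)) for a in a4
        ]

    def test_taxonomy_mismatch_rejected_before_processing(self, planted):
        from pmprofiler.io_formats import TaxonomyMap

        _, db, index = planted
        with pytest.raises(ValueError, match="missing from the taxonomy"):
            profile_sample([], index, TaxonomyMap({}), mode="hwl")


class TestRankCollapse:
    def test_genus_counts_sum_species_counts(self):
        prof = Profile(
            "s",
            "HWL",
            counts={
                "k__B;p__P;c__C;o__O;f__F;g__G;s__A": 3,
                "k__B;p__P;c__C;o__O;f__F;g__G;s__B": 2,
                "k__B;p__P;c__C;o__O;f__F;g__H;s__C": 4,
            },
            n_reads=9,
        )
        genus = prof.collapse("genus")
        assert genus["k__B;p__P;c__C;o__O;f__F;g__G"] == 5
        assert genus["k__B;p__P;c__C;o__O;f__F;g__H"] == 4
        assert sum(genus.values()) == sum(prof.collapse("species").values())

    def test_shallow_lineages_dropped_at_deeper_rank(self):
        prof = Profile("s", "LCA", counts={"k__B;p__P": 5}, n_reads=5)
        assert prof.collapse("species") == {}
        assert prof.collapse("phylum") == {"k__B;p__P": 5}


class TestCli:
    @pytest.fixture()
    def workdir(self, tmp_path, planted):
        from pmprofiler.io_formats import write_sequences, write_taxonomy_map
        import numpy as np

        cfg, db, _ = planted
        refs = str(tmp_path / "refs.fasta")
        tax = str(tmp_path / "tax.tsv")
        reads_path = str(tmp_path / "sample.fastq")
        write_sequences(db.records, refs, format="fasta")
        write_taxonomy_map(db.taxonomy, tax)
        reads, _ = simulate_sample(db, cfg, rng=np.random.default_rng(13))
        write_sequences(reads, reads_path, format="fastq")
        return tmp_path, refs, tax, reads_path

    def test_index_then_profile(self, workdir):
        tmp_path, refs, tax, reads_path = workdir
        db_path = str(tmp_path / "db.pmidx")
        assert run_cli(["index", "-r", refs, "-t", tax, "-k", "15", "-o", db_path]) == 0
        outdir = str(tmp_path / "out")
        assert run_cli(
            ["profile", "-d", db_path, "-i", reads_path, "-o", outdir, "-m", "both"]
        ) == 0
        hwl = read_profile(os.path.join(outdir, "sample.hwl.profile.tsv"))
        assert hwl.n_reads == 10
        manifest = json.load(open(os.path.join(outdir, "sample.manifest.json")))
        assert manifest["parameters"]["mode"] == "both"
        assert set(manifest["input_checksums"]) == {db_path, reads_path}

    def test_missing_required_option_exits_2(self):
        assert run_cli(["profile", "-i", "nowhere.fq", "-o", "x"]) == 2

    def test_runs_are_deterministic(self, workdir):
        tmp_path, refs, tax, reads_path = workdir
        outputs = []
        for run in ("a", "b"):
            db_path = str(tmp_path / f"db{run}.pmidx")
            run_cli(["index", "-r", refs, "-t", tax, "-o", db_path])
            outdir = str(tmp_path / f"out{run}")
            run_cli(["profile", "-d", db_path, "-i", reads_path, "-o", outdir,
                     "--threads", "4" if run == "a" else "1"])
            outputs.append(
                (
                    open(os.path.join(outdir, "sample.hwl.profile.tsv")).read(),
                    open(os.path.join(outdir, "sample.annotations.tsv")).read(),
                )
            )
        assert outputs[0] == outputs[1]

    def test_simulate_and_evaluate_roundtrip(self, tmp_path):
        simdir = str(tmp_path / "sim")
        cfgfile = tmp_path / "sim.yaml"
        cfgfile.write_text(
            "n_species: 6\nn_sample_species: 6\nn_reads: 20\nseed: 4\n"
            "near_identical_fraction: 0.0\n"
        )
        assert run_cli(["simulate", "--config", str(cfgfile), "--out", simdir]) == 0
        db_path = str(tmp_path / "db.pmidx")
        assert run_cli(["index", "-r", os.path.join(simdir, "refs.fasta"),
                        "-t", os.path.join(simdir, "tax.tsv"), "-o", db_path]) == 0
        outdir = str(tmp_path / "out")
        assert run_cli(["profile", "-d", db_path, "-i", os.path.join(simdir, "sample1.fastq"),
                        "-o", outdir]) == 0
        assert run_cli(["evaluate",
                        "--profile", os.path.join(outdir, "sample1.hwl.profile.tsv"),
                        "--truth", os.path.join(simdir, "truth.tsv"),
                        "--rank", "species"]) == 0
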