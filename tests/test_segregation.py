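"""Recessive discovery filter: unit cases, brute-force oracle, properties.

The oracle is a naive per-gene transcription of the selection rule — every
case homozygous (depth-passing) at some gene variant or heterozygous at two
or more, no control matching the same pattern over the implicated variants
— written directly against raw genotype matrices, independent of the
implementation's data structures.
"""

from __future__ import annotations

import itertools
import random

import pytest

from minkmap.fixtures import SURROGATE_GENE_ID, rab38_surrogate_gene, table1_fixture
from minkmap.models import (
    CohortGenotypes,
    GenotypeCall,
    GenotypeClass,
    Role,
    Sample,
    TranscriptModel,
    Variant,
)
from minkmap.segregation import (
    ConfigurationError,
    FilterParams,
    compound_het_groups,
    genotype_class,
    homozygous_site_candidates,
    passes_depth,
    recessive_candidates,
)

# --- helpers ---------------------------------------------------------------

CLASS_CODES = {  # (allele_a, allele_b) prototypes per class code
    "R": (0, 0), "H": (0, 1), "A": (1, 1), "M": (None, None),
}


def make_cohort(matrix, roles, depths=None):
    """Cohort from a class-code matrix: rows=variants, cols=samples.

    ``matrix`` rows are strings over R/H/A/M; ``roles`` a string over
    c (case), n (control), u (unassigned). Default depth 10.
    """
    n_var, n_smp = len(matrix), len(roles)
    variants = [
        Variant("chr1", 100 + 10 * i, "A", "T", id=f"v{i + 1}")
        for i in range(n_var)
    ]
    role_map = {"c": Role.CASE, "n": Role.CONTROL, "u": Role.UNASSIGNED}
    samples = [
        Sample(f"s{j + 1}", "", role_map[roles[j]]) for j in range(n_smp)
    ]
    calls = []
    for i in range(n_var):
        row = []
        for j in range(n_smp):
            a, b = CLASS_CODES[matrix[i][j]]
            dp = 10 if depths is None else depths[i][j]
            row.append(GenotypeCall(a, b, depth=dp))
        calls.append(row)
    return CohortGenotypes(variants, samples, calls)


def gene_transcripts(spans):
    """One single-exon transcript per (gene_id, start_pos, end_pos) 1-based."""
    return [
        TranscriptModel(g, f"{g}.t1", "chr1", "+", [(s - 1, e)], [])
        for g, s, e in spans
    ]


ONE_GENE = gene_transcripts([("G", 50, 200)])
TWO_GENES = gene_transcripts([("G1", 50, 140), ("G2", 141, 300)])


# --- unit behaviour --------------------------------------------------------


class TestGenotypeClass:
    @pytest.mark.parametrize(
        "call,expected",
        [
            (GenotypeCall(1, 1, 40), GenotypeClass.HOM_ALT),
            (GenotypeCall(0, 1, 9), GenotypeClass.HET),
            (GenotypeCall(1, 0, 9), GenotypeClass.HET),
            (GenotypeCall(0, 0, 3), GenotypeClass.HOM_REF),
            (GenotypeCall(None, None), GenotypeClass.MISSING),
            (GenotypeCall(1, None), GenotypeClass.MISSING),
        ],
    )
    def test_classification(self, call, expected):
        assert genotype_class(call) is expected


class TestPassesDepth:
    def test_boundary_is_exclusive(self):
        params = FilterParams()
        assert passes_depth(GenotypeCall(0, 1, depth=3), params)
        assert not passes_depth(GenotypeCall(0, 1, depth=2), params)

    def test_missing_depth_fails(self):
        assert not passes_depth(GenotypeCall(0, 1, depth=None), FilterParams())


class TestCompoundHetGroups:
    def test_two_passing_hets_form_a_group(self):
        cohort = make_cohort(["HR", "HR", "RR"], "cu")
        groups = compound_het_groups(cohort, "s1", ONE_GENE)
        assert list(groups) == ["G"]
        assert [v.id for v in groups["G"]] == ["v1", "v2"]

    def test_single_het_is_not_a_group(self):
        cohort = make_cohort(["HR", "RR"], "cu")
        assert compound_het_groups(cohort, "s1", ONE_GENE) == {}

    def test_low_depth_het_drops_out(self):
        """DP=2 fails the strict 'greater than 2' bound, breaking the pair."""
        depths = [[5, 10], [2, 10]]
        cohort = make_cohort(["HR", "HR"], "cu", depths)
        assert compound_het_groups(cohort, "s1", ONE_GENE) == {}

    def test_unknown_sample_rejected(self):
        cohort = make_cohort(["HR"], "cu")
        with pytest.raises(KeyError, match="nobody"):
            compound_het_groups(cohort, "nobody", ONE_GENE)


class TestRecessiveCandidates:
    def test_homozygous_in_cases_absent_in_controls(self):
        cohort = make_cohort(["AARR"], "ccnn")
        result = recessive_candidates(cohort, ONE_GENE)
        assert result.gene_ids == ["G"]
        entry = result.entries[0]
        assert entry.mode == "homozygous"
        assert entry.per_case_evidence == {"s1": "homozygous", "s2": "homozygous"}

    def test_mixed_hom_and_compound_het_cases(self):
        """One case homozygous, the other double-het; carrier controls ok."""
        cohort = make_cohort(
            ["AHRH",   # v1: case1 hom, case2 het, ctrl2 het carrier
             "RHRR"],  # v2: case2 het
            "ccnn",
        )
        result = recessive_candidates(cohort, ONE_GENE)
        assert result.gene_ids == ["G"]
        entry = result.entries[0]
        assert entry.mode == "mixed"
        assert entry.per_case_evidence == {"s1": "homozygous", "s2": "compound_het"}
        assert [v.id for v in entry.variants] == ["v1", "v2"]

    def test_control_homozygous_excludes_gene(self):
        cohort = make_cohort(["AAAR"], "ccnn")
        assert recessive_candidates(cohort, ONE_GENE).gene_ids == []

    def test_control_compound_het_excludes_gene(self):
        cohort = make_cohort(["HHHR", "HHHR"], "ccnn")
        assert recessive_candidates(cohort, ONE_GENE).gene_ids == []

    def test_case_without_support_fails_gene(self):
        cohort = make_cohort(["ARRR"], "ccnn")
        assert recessive_candidates(cohort, ONE_GENE).gene_ids == []

    def test_missing_case_strict_vs_relaxed(self):
        cohort = make_cohort(["AMRR"], "ccnn")
        strict = recessive_candidates(cohort, ONE_GENE, FilterParams())
        relaxed = recessive_candidates(
            cohort, ONE_GENE,
            FilterParams(require_called_in_all_cases=False),
        )
        assert strict.gene_ids == []
        assert relaxed.gene_ids == ["G"]

    def test_no_cases_or_controls_rejected(self):
        cohort = make_cohort(["AR"], "cu")
        with pytest.raises(ConfigurationError):
            recessive_candidates(cohort, ONE_GENE)

    def test_variant_outside_gene_span_ignored(self):
        transcripts = gene_transcripts([("G", 50, 105)])
        cohort = make_cohort(["AARR", "AARR"], "ccnn")  # v2 at pos 110
        result = recessive_candidates(cohort, transcripts)
        assert [v.id for v in result.entries[0].variants] == ["v1"]


class TestHomozygousSiteMode:
    def test_per_variant_rule(self):
        cohort = make_cohort(["AARR", "AHRR", "AAAR"], "ccnn")
        hits = homozygous_site_candidates(cohort)
        assert [v.id for v in hits] == ["v1"]


# --- brute-force oracle ----------------------------------------------------


def oracle_candidates(matrix, depths, roles, gene_of, min_dp, require_all):
    """Naive per-gene transcription of the selection rule."""
    n_var = len(matrix)
    cases = [j for j, r in enumerate(roles) if r == "c"]
    controls = [j for j, r in enumerate(roles) if r == "n"]
    genes = sorted(set(gene_of))
    out = []
    for gene in genes:
        gvars = [i for i in range(n_var) if gene_of[i] == gene]

        def usable(i, j):
            return matrix[i][j] != "M" and depths[i][j] is not None \
                and depths[i][j] > min_dp

        def support(j):
            homs = [i for i in gvars if matrix[i][j] == "A" and usable(i, j)]
            if homs:
                return homs
            hets = [i for i in gvars if matrix[i][j] == "H" and usable(i, j)]
            return hets if len(hets) >= 2 else None

        implicated = set()
        unsupported = []
        failed = False
        for j in cases:
            sup = support(j)
            if sup is None:
                if require_all:
                    failed = True
                    break
                unsupported.append(j)
                continue
            implicated.update(sup)
        if failed or not implicated:
            continue
        if any(usable(i, j) for j in unsupported for i in implicated):
            continue
        excluded = False
        for j in controls:
            homs = [i for i in implicated if matrix[i][j] == "A" and usable(i, j)]
            hets = [i for i in implicated if matrix[i][j] == "H" and usable(i, j)]
            if homs or len(hets) >= 2:
                excluded = True
                break
        if not excluded:
            out.append(gene)
    return out


def run_both(matrix, depths, roles, gene_of, min_dp=2, require_all=True):
    # give each gene a disjoint position block so spans cannot overlap
    genes = sorted(set(gene_of))
    base = {g: 100 + 1000 * k for k, g in enumerate(genes)}
    offsets: dict[str, int] = {}
    positions = []
    for g in gene_of:
        offsets[g] = offsets.get(g, 0) + 10
        positions.append(base[g] + offsets[g])
    n_smp = len(roles)
    role_map = {"c": Role.CASE, "n": Role.CONTROL, "u": Role.UNASSIGNED}
    variants = [
        Variant("chr1", positions[i], "A", "T", id=f"v{i + 1}")
        for i in range(len(matrix))
    ]
    samples = [Sample(f"s{j + 1}", "", role_map[roles[j]]) for j in range(n_smp)]
    calls = [
        [
            GenotypeCall(*CLASS_CODES[matrix[i][j]], depth=depths[i][j])
            for j in range(n_smp)
        ]
        for i in range(len(matrix))
    ]
    cohort = CohortGenotypes(variants, samples, calls)
    transcripts = gene_transcripts(
        [(g, base[g], base[g] + 999) for g in genes]
    )
    params = FilterParams(min_depth_exclusive=min_dp,
                          require_called_in_all_cases=require_all)
    got = recessive_candidates(cohort, transcripts, params).gene_ids
    want = oracle_candidates(matrix, depths, roles, gene_of, min_dp, require_all)
    return got, want


def test_exhaustive_small_cohorts_match_oracle():
    """All 4^6 class matrices for 3 samples x 2 variants, one gene."""
    roles = "ccn"
    for cells in itertools.product("RHAM", repeat=6):
        matrix = ["".join(cells[0:3]), "".join(cells[3:6])]
        depths = [[10] * 3, [10] * 3]
        got, want = run_both(matrix, depths, roles, ["G", "G"])
        assert got == want, matrix


def test_exhaustive_depth_boundary_matches_oracle():
    """All depth combinations around the DP>2 bound at a single hom site."""
    for dp in itertools.product([None, 0, 2, 3, 10], repeat=3):
        got, want = run_both(["AAR"], [list(dp)], "ccn", ["G"])
        assert got == want, dp


def test_random_cohorts_match_oracle():
    """Random cohorts up to 5 samples x 8 variants x 2 genes, mixed depths."""
    rng = random.Random(7)
    for _ in range(400):
        n_smp = rng.randint(2, 5)
        n_var = rng.randint(1, 8)
        roles = "".join(
            rng.choice("ccn") for _ in range(n_smp - 2)
        ) + "cn"  # always >=1 case and >=1 control
        matrix = [
            "".join(rng.choice("RHAM") for _ in range(n_smp))
            for _ in range(n_var)
        ]
        depths = [
            [rng.choice([None, 0, 2, 3, 10, 40]) for _ in range(n_smp)]
            for _ in range(n_var)
        ]
        gene_of = [rng.choice(["G1", "G2"]) for _ in range(n_var)]
        require_all = rng.random() < 0.5
        got, want = run_both(matrix, depths, roles, gene_of,
                             require_all=require_all)
        assert got == want, (matrix, depths, roles, gene_of, require_all)


# --- structural properties -------------------------------------------------


def test_raising_depth_threshold_never_adds_case_support():
    """Per-case supporting evidence shrinks as the depth bound rises.

    (The full candidate set is not monotone in the threshold: a control's
    exclusion can itself fall below depth. Case-side support is.)
    """
    rng = random.Random(11)
    for _ in range(100):
        matrix = ["".join(rng.choice("RHAM") for _ in range(4)) for _ in range(5)]
        depths = [
            [rng.choice([None, 1, 3, 5, 9]) for _ in range(4)] for _ in range(5)
        ]
        cohort = make_cohort(matrix, "ccnn", depths)
        prev = None
        for min_dp in (0, 2, 4, 8):
            groups = {
                sid: set(v.id for v in compound_het_groups(
                    cohort, sid, ONE_GENE,
                    FilterParams(min_depth_exclusive=min_dp),
                ).get("G", []))
                for sid in ("s1", "s2")
            }
            if prev is not None:
                for sid in groups:
                    assert groups[sid] <= prev[sid]
            prev = groups


def test_adding_samples_only_removes_genes():
    """Extra cases or controls can only shrink the candidate set."""
    rng = random.Random(13)
    for _ in range(200):
        n_var = rng.randint(1, 5)
        matrix = ["".join(rng.choice("RHA") for _ in range(3)) for _ in range(n_var)]
        depths = [[10] * 3 for _ in range(n_var)]
        gene_of = ["G1" if i % 2 == 0 else "G2" for i in range(n_var)]
        base, _ = run_both(matrix, depths, "ccn", gene_of)
        for extra_role in ("c", "n"):
            extended = [
                row + rng.choice("RHA") for row in matrix
            ]
            ext_depths = [row + [10] for row in depths]
            got, _ = run_both(extended, ext_depths, "ccn" + extra_role, gene_of)
            assert set(got) <= set(base), (matrix, extended, extra_role)


# --- packaged genotyping-table fixture -------------------------------------


def test_table1_fixture_yields_unique_candidate_gene():
    """The surrogate gene is the unique candidate on the published table.

    The single royal-pastel deletion carrier is heterozygous only and must
    not exclude the gene.
    """
    cohort, _ = table1_fixture()
    _, model, _, _ = rab38_surrogate_gene()
    result = recessive_candidates(cohort, [model])
    assert result.gene_ids == [SURROGATE_GENE_ID]
    entry = result.entries[0]
    assert len(entry.variants) == 2
    assert set(entry.per_case_evidence.values()) == {"homozygous", "compound_het"}
    assert len(entry.per_case_evidence) == 8
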