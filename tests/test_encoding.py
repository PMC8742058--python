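import pytest
from hypothesis import given, settings, strategies as st

from qmarkush.encoding import (
    CyclicGrammarError,
    MarkushPatent,
    alternative_notations,
    build_code_table,
    count_claims,
    decode_bitstring,
    encode_smiles,
    enumerate_claims,
    load_code_table,
    load_patent,
    load_smiles_list,
    required_qubits,
    save_code_table,
    tokenize,
)


class TestCodeTable:
    def test_reference_assignment(self, reference_table):
        assert reference_table.entries == {"C": "00", "O": "10"}
        assert reference_table.empty_code == "11"
        assert reference_table.bits_per_symbol == 2

    def test_smallest_table(self):
        t = build_code_table(["A"])
        assert t.bits_per_symbol == 1
        assert t.entries == {"A": "0"}
        assert t.empty_code == "1"

    def test_width_grows_with_alphabet(self):
        # 5 symbols + the padding symbol need 3 bits
        assert build_code_table(list("ABCDE")).bits_per_symbol == 3

    def test_codes_assigned_in_input_order(self):
        t = build_code_table(["X", "Y"])
        assert t.entries == {"X": "00", "Y": "01"}

    def test_duplicate_symbol_rejected(self):
        with pytest.raises(ValueError, match="C"):
            build_code_table(["C", "O", "C"])

    def test_assignment_collision_rejected(self):
        with pytest.raises(ValueError):
            build_code_table(["C", "O"], assignments={"C": "11"})

    def test_tsv_round_trip(self, reference_table, tmp_path):
        path = tmp_path / "table.tsv"
        save_code_table(reference_table, str(path))
        back = load_code_table(str(path))
        assert back == reference_table


class TestRequiredQubits:
    @pytest.mark.parametrize(
        "length,symbols,expected",
        [(3, 4, 6), (4, 4, 8), (1, 2, 1), (5, 8, 15)],
    )
    def test_rule(self, length, symbols, expected):
        assert required_qubits(length, symbols) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            required_qubits(0, 4)


class TestEncodeDecode:
    def test_occ_is_padded_to_10000011(self, reference_table):
        assert encode_smiles("OCC", reference_table, 4).bitstring == "10000011"

    def test_ccco_is_basis_state_2(self, reference_table):
        assert encode_smiles("CCCO", reference_table, 4).basis_index == 2

    def test_occc_is_basis_state_128(self, reference_table):
        enc = encode_smiles("OCCC", reference_table, 4)
        assert enc.bitstring == "10000000"
        assert enc.basis_index == 128

    def test_empty_string_is_all_padding(self, reference_table):
        assert encode_smiles("", reference_table, 2).bitstring == "1111"

    def test_unknown_token_rejected(self, reference_table):
        with pytest.raises(KeyError, match="N"):
            encode_smiles("CN", reference_table, 4)

    def test_over_length_rejected(self, reference_table):
        with pytest.raises(ValueError, match="max_len"):
            encode_smiles("CCCCC", reference_table, 4)

    def test_decode_inverts_encode(self, reference_table):
        assert decode_bitstring("10000000", reference_table) == "OCCC"
        assert decode_bitstring("1111", reference_table) == ""

    def test_code_after_padding_rejected(self, reference_table):
        with pytest.raises(ValueError, match="padding"):
            decode_bitstring("11000000", reference_table)

    def test_unassigned_code_rejected(self, reference_table):
        with pytest.raises(KeyError):
            decode_bitstring("01", reference_table)

    def test_multi_character_tokens(self):
        t = build_code_table(["C", "Cl", "O"])
        enc = encode_smiles("CClO", t, 4, tokens=["C", "Cl", "O"])
        assert len(tokenize("CClO", ["C", "Cl", "O"])) == 3
        assert decode_bitstring(enc.bitstring, t) == "CClO"

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="CO", max_size=4))
    def test_round_trip_property(self, reference_table, s):
        enc = encode_smiles(s, reference_table, 4)
        assert len(enc.bitstring) == 8
        assert decode_bitstring(enc.bitstring, reference_table) == s
        assert enc.basis_index == int(enc.bitstring, 2)


INTRO_RULES = {
    "R1": ["{R}"],
    "R2": ["{R}*{R3}", "{R}*{R4}", "{R4}*{R5}"],
    "R3": ["{R}", "{R}*{R6}", "{R}*{R7}"],
    "R4": ["{R}"],
    "R5": ["{R}"],
    "R6": ["{R}"],
    "R7": ["{R}"],
}


class TestGrammar:
    def test_single_production(self):
        p = MarkushPatent(core="CC{R1}", rules={"R1": ["CO"]})
        assert enumerate_claims(p) == ["CCCO"]
        assert count_claims(p) == 1

    def test_nested_grammar_with_one_terminal(self):
        # the nested R2 grammar has count(R3) = 3, so count(R2) = 3 + 1 + 1
        # = 5 derivations; with a single terminal the five derivations
        # collapse onto two distinct strings, which enumeration deduplicates
        p = MarkushPatent(core="{R2}", rules=INTRO_RULES, terminals={"R": ["C"]})
        assert count_claims(p) == 5
        assert enumerate_claims(p) == ["C*C", "C*C*C"]

    def test_nested_grammar_distinct_derivations_enumerate_fully(self):
        # tagging each production makes every derivation a distinct string,
        # so enumeration agrees with the derivation count of 5
        rules = dict(INTRO_RULES)
        rules["R2"] = ["a{R}*{R3}", "b{R}*{R4}", "c{R4}*{R5}"]
        rules["R3"] = ["d{R}", "e{R}*{R6}", "f{R}*{R7}"]
        p = MarkushPatent(core="{R2}", rules=rules, terminals={"R": ["C"]})
        assert count_claims(p) == 5
        assert len(enumerate_claims(p)) == 5

    def test_full_nested_grammar_counts(self):
        # core with both side chains, against brute-force expansion
        p = MarkushPatent(core="{R1}*{R2}", rules=INTRO_RULES, terminals={"R": ["C"]})
        assert count_claims(p) == 1 * 5

    def test_count_scales_with_terminal_choices(self):
        p = MarkushPatent(core="{R2}", rules=INTRO_RULES,
                          terminals={"R": ["C", "O"]})
        # count(R3) = 2 + 2*2 + 2*2 = 10; count(R2) = 2*10 + 2*2 + 2*2 = 28
        assert count_claims(p) == 28

    def test_enumeration_is_deterministic_and_deduplicated(self):
        p = MarkushPatent(core="{A}", rules={"A": ["X", "X", "Y"]})
        assert enumerate_claims(p) == ["X", "Y"]
        assert count_claims(p) == 3  # derivations, not distinct strings

    def test_limit_truncates(self):
        p = MarkushPatent(core="{A}", rules={"A": ["X", "Y", "Z"]})
        assert enumerate_claims(p, limit=2) == ["X", "Y"]

    def test_cycle_rejected_with_names(self):
        with pytest.raises(CyclicGrammarError, match="A"):
            MarkushPatent(core="{A}", rules={"A": ["{B}"], "B": ["{A}"]})

    def test_undefined_reference_rejected(self):
        with pytest.raises(ValueError, match="R9"):
            MarkushPatent(core="{R9}")

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_count_matches_enumeration_on_random_acyclic_grammars(self, data):
        # grammars built so that every derivation yields a distinct string:
        # each production is tagged with a unique literal
        n_rules = data.draw(st.integers(1, 4))
        names = [f"G{i}" for i in range(n_rules)]
        rules = {}
        tag = 0
        for i, name in enumerate(names):
            prods = []
            n_prods = data.draw(st.integers(1, 3))
            for _ in range(n_prods):
                refs = data.draw(
                    st.lists(st.sampled_from(names[i + 1:] or ["_none"]),
                             max_size=2))
                body = f"t{tag}." + "".join(
                    "{%s}" % r for r in refs if r != "_none")
                prods.append(body)
                tag += 1
            rules[name] = prods
        p = MarkushPatent(core="{G0}", rules=rules)
        assert count_claims(p) == len(enumerate_claims(p))


class TestAlternativeNotations:
    def test_chain_and_its_reversal(self):
        assert alternative_notations("CCCO") == {"CCCO", "OCCC"}
        assert alternative_notations("CCO") == {"CCO", "OCC"}

    def test_palindrome_collapses(self):
        assert alternative_notations("CC") == {"CC"}

    def test_branched_input_rejected(self):
        with pytest.raises(ValueError, match="branch"):
            alternative_notations("CC(C)O")

    def test_ring_closure_rejected(self):
        with pytest.raises(ValueError):
            alternative_notations("C1CCCCC1")

    def test_pluggable_expander(self):
        out = alternative_notations("C1CC1", expander=lambda s: {s, "custom"})
        assert out == {"C1CC1", "custom"}

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="CON", min_size=1, max_size=6))
    def test_involution_closure(self, s):
        alts = alternative_notations(s)
        for t in alts:
            assert alternative_notations(t) == alts


class TestFileFormats:
    def test_patent_yaml_round_trip(self, tmp_path):
        from qmarkush.encoding import save_patent

        p = MarkushPatent(core="CC{R1}", rules={"R1": ["CO", "{R}"]},
                          terminals={"R": ["C"]})
        path = tmp_path / "p.yaml"
        save_patent(p, str(path))
        assert load_patent(str(path)) == p

    def test_smiles_list_ignores_comments(self, tmp_path):
        path = tmp_path / "list.smi"
        path.write_text("CCO  # ethanol\n\n# blank above\nOCC\n")
        assert load_smiles_list(str(path)) == ["CCO", "OCC"]
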