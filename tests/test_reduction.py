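import numpy as np
import pytest

import kindraft as kd


def retained_balances(network, fluxes, retained_ids):
    """Net production of each retained internal species under the fluxes."""
    S = kd.stoichiometric_matrix(network)
    Sv = S.dot(fluxes)
    return {sid: Sv[S.row_ids.index(sid)] for sid in retained_ids
            if sid in S.row_ids}


class TestHandDerivedEliminations:
    def test_chain_elimination_yields_single_lump(self, chain3):
        net, fluxes, _ = chain3
        result = kd.reduce_network(net, fluxes, ["X2"])
        assert {s.id for s in result.reduced_network.species} == {"X1", "X3"}
        lump = result.reduced_network.get_reaction("lump__R1__R2")
        assert lump.stoichiometry == {"X1": -1.0, "X3": 1.0}
        assert result.reduced_fluxes["lump__R1__R2"] == pytest.approx(1.0)
        assert result.lump_map == {"lump__R1__R2": [("R1", 1.0), ("R2", 1.0)]}
        assert result.max_residual() == 0.0

    def test_branch_point_elimination_splits_flux_proportionally(self, branched):
        net, fluxes, _ = branched
        result = kd.reduce_network(net, fluxes, ["M"])
        ids = {r.id for r in result.reduced_network.reactions}
        assert "lump__R1__R2" in ids and "lump__R1__R3" in ids
        assert result.reduced_network.get_reaction(
            "lump__R1__R2").stoichiometry == {"X": 1.0}
        assert result.reduced_network.get_reaction(
            "lump__R1__R3").stoichiometry == {"Y": 1.0}
        assert result.reduced_fluxes["lump__R1__R2"] == pytest.approx(1.0)
        assert result.reduced_fluxes["lump__R1__R3"] == pytest.approx(1.0)
        # balances of the retained species are untouched
        before = retained_balances(net, fluxes, ["X", "Y", "P", "Q"])
        after = retained_balances(
            result.reduced_network, result.reduced_fluxes, ["X", "Y", "P", "Q"]
        )
        for sid in before:
            assert after[sid] == pytest.approx(before[sid], abs=1e-9)

    def test_sequential_chain_removal_collapses_to_single_reaction(self):
        net, fluxes, _ = kd.toy_linear_chain(4, 2.5)
        result = kd.reduce_network(net, fluxes, ["X2", "X3"])
        assert {s.id for s in result.reduced_network.species} == {"X1", "X4"}
        lumped = [r for r in result.reduced_network.reactions
                  if r.id.startswith("lump__")]
        assert len(lumped) == 1
        assert lumped[0].stoichiometry == {"X1": -1.0, "X4": 1.0}
        assert result.reduced_fluxes[lumped[0].id] == pytest.approx(2.5)

    def test_chain_removal_order_independent(self):
        net, fluxes, _ = kd.toy_linear_chain(4, 1.0)
        a = kd.reduce_network(net, fluxes, ["X2", "X3"])
        b = kd.reduce_network(net, fluxes, ["X3", "X2"])
        sa = sorted(tuple(sorted(r.stoichiometry.items()))
                    for r in a.reduced_network.reactions)
        sb = sorted(tuple(sorted(r.stoichiometry.items()))
                    for r in b.reduced_network.reactions)
        assert sa == sb


class TestErrorCases:
    def test_unknown_species_named_in_error(self, chain3):
        net, fluxes, _ = chain3
        with pytest.raises(kd.MatchError, match="nonexistent"):
            kd.reduce_network(net, fluxes, ["nonexistent"])

    def test_zero_throughput_with_active_reactions_is_error(self, chain3):
        net, fluxes, _ = chain3
        # X2's producer carries no flux while its consumer is active, so
        # the lumping weights would be undefined
        broken = kd.FluxSet({"R_in": 0.0, "R1": 0.0, "R2": 1.0, "R_out": 1.0})
        with pytest.raises(kd.ReductionError, match="zero reference throughput"):
            kd.reduce_network(net, broken, ["X2"])

    def test_dead_species_with_all_zero_fluxes_is_deleted(self):
        net, fluxes, _ = kd.toy_linear_chain(3, 1.0)
        net.species.append(kd.Species("D", compartment="cell"))
        net.reactions.append(kd.Reaction("R_dead", {"X1": -1.0, "D": 1.0}))
        net.reactions.append(kd.Reaction("R_dead2", {"D": -1.0}))
        fluxes.values.update({"R_dead": 0.0, "R_dead2": 0.0})
        result = kd.reduce_network(net, fluxes, ["D"])
        assert "D" not in {s.id for s in result.reduced_network.species}
        assert "R_dead" not in {r.id for r in result.reduced_network.reactions}
        assert result.max_residual() <= 1e-9

    def test_hub_elimination_capped(self):
        # star: 3 producers and 3 consumers of H -> 9 lumps, cap of 4 trips
        species = [kd.Species("H", compartment="c")]
        reactions, flux = [], {}
        for i in range(3):
            reactions.append(kd.Reaction(f"Rp{i}", {"H": 1.0}))
            reactions.append(kd.Reaction(f"Rc{i}", {"H": -1.0}))
            flux[f"Rp{i}"] = flux[f"Rc{i}"] = 1.0
        net = kd.MetabolicNetwork(
            compartments=[kd.Compartment("c")], species=species,
            reactions=reactions,
        )
        with pytest.raises(kd.ReductionError, match="hub"):
            kd.reduce_network(net, kd.FluxSet(flux), ["H"], pair_cap=4)

    def test_negative_fluxes_rejected(self, chain3):
        net, _, _ = chain3
        fluxes = kd.FluxSet({"R_in": 1.0, "R1": -1.0, "R2": 1.0, "R_out": 1.0})
        with pytest.raises(kd.ReductionError, match="normalize_directionality"):
            kd.reduce_network(net, fluxes, ["X2"])

    def test_uncovered_reaction_rejected(self, chain3):
        net, _, _ = chain3
        with pytest.raises(kd.ReductionError, match="cover"):
            kd.reduce_network(net, kd.FluxSet({"R_in": 1.0}), ["X2"])


class TestRandomFixtureProperties:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_steady_state_and_throughput_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        net, fluxes, _ = kd.random_consistent_network(
            kd.FixtureSpec(n_species=n, n_reactions=n + 3, seed=seed)
        )
        remove = [f"S{int(rng.integers(1, n + 1))}"]
        result = kd.reduce_network(net, fluxes, remove)
        assert result.max_residual() <= 1e-9
        retained = [s.id for s in result.reduced_network.species]
        before = retained_balances(net, fluxes, retained)
        after = retained_balances(
            result.reduced_network, result.reduced_fluxes, retained
        )
        for sid in retained:
            assert after[sid] == pytest.approx(before[sid], abs=1e-9)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_lump_weights_reconstruct_original_fluxes(self, seed):
        net, fluxes, _ = kd.random_consistent_network(
            kd.FixtureSpec(n_species=6, n_reactions=9, seed=seed)
        )
        remove = ["S3"]
        result = kd.reduce_network(net, fluxes, remove)
        contributions: dict[str, float] = {}
        for lump_id, parts in result.lump_map.items():
            v = result.reduced_fluxes[lump_id]
            for orig, weight in parts:
                assert weight > 0
                contributions[orig] = contributions.get(orig, 0.0) + weight * v
        for orig, total in contributions.items():
            assert total == pytest.approx(fluxes[orig], abs=1e-9)


class TestReductionArchive:
    def test_archive_has_exactly_two_members(self, tmp_path, chain3):
        import zipfile

        net, fluxes, _ = chain3
        result = kd.reduce_network(net, fluxes, ["X2"])
        path = tmp_path / "reduced.zip"
        kd.write_reduction_archive(result, path)
        with zipfile.ZipFile(path) as zf:
            assert len(zf.namelist()) == 2

    def test_archive_round_trip(self, tmp_path, branched):
        net, fluxes, _ = branched
        result = kd.reduce_network(net, fluxes, ["M"])
        path = tmp_path / "reduced.zip"
        kd.write_reduction_archive(result, path)
        back_net, back_fluxes = kd.read_reduction_archive(path)
        assert kd.structural_diff(result.reduced_network, back_net) == []
        assert back_fluxes.values == pytest.approx(result.reduced_fluxes.values)

    def test_inconsistent_result_rejected_before_writing(self, tmp_path, chain3):
        net, fluxes, _ = chain3
        result = kd.reduce_network(net, fluxes, ["X2"])
        result.reduced_fluxes.values["lump__R1__R2"] = 5.0  # break steady state
        with pytest.raises(kd.ReductionError, match="steady state"):
            kd.write_reduction_archive(result, tmp_path / "bad.zip")
        assert not (tmp_path / "bad.zip").exists()

    def test_archives_are_byte_identical_across_runs(self, tmp_path, chain3):
        net, fluxes, _ = chain3
        result = kd.reduce_network(net, fluxes, ["X2"])
        p1, p2 = tmp_path / "a.zip", tmp_path / "b.zip"
        kd.write_reduction_archive(result, p1)
        kd.write_reduction_archive(result, p2)
        assert p1.read_bytes() == p2.read_bytes()
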