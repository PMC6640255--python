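import numpy as np
import pytest

from spendgrid import (
    GeneratorConfig,
    MonthlySpendMatrix,
    OrderAssignment,
    all_subgroup_occupancy,
    generate_monthly_matrix,
    segment_counts,
    segment_spend,
    select_top_fraction,
    yearly_totals,
)


@pytest.fixture
def toy_matrix():
    """Two beneficiaries, three months: A=[5,0,7], B=[2,3,1] (cents)."""
    return MonthlySpendMatrix(("A", "B"), np.array([[5, 0, 7], [2, 3, 1]]))


@pytest.fixture
def toy_orders(toy_matrix):
    return OrderAssignment.from_matrix(toy_matrix)


@pytest.fixture(scope="session")
def synth_study():
    """A segmented synthetic study at n=1000: matrix, cohort, orders, grids."""
    config = GeneratorConfig(n_beneficiaries=1000, seed=20120)
    matrix, eligibility = generate_monthly_matrix(config)
    selection = select_top_fraction(yearly_totals(matrix), 0.10)
    orders = OrderAssignment.from_matrix(matrix, selection.cohort_ids)
    spend_grid = segment_spend(matrix, orders, selection.cohort_ids)
    count_grid = segment_counts(orders, selection.cohort_ids)
    occupancies = all_subgroup_occupancy(matrix.subset(selection.cohort_ids), orders)
    return {
        "config": config,
        "matrix": matrix,
        "eligibility": eligibility,
        "selection": selection,
        "orders": orders,
        "spend_grid": spend_grid,
        "count_grid": count_grid,
        "occupancies": occupancies,
    }
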