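import numpy as np
import pandas as pd
import pytest

from phenogs import GenotypeMatrix, TrialTable


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """8 lines x 6 markers, no missing calls, deterministic."""
    rng = np.random.default_rng(42)
    dosage = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
    return GenotypeMatrix(
        line_ids=[f"L{i}" for i in range(8)],
        marker_ids=[f"M{j}" for j in range(6)],
        dosage=dosage,
    )


def balanced_trial(n_geno=60, n_env=4, n_rep=2, s2g=1.0, s2ge=0.5, s2e=2.0,
                   seed=1, mu=5.0) -> TrialTable:
    """Balanced replicated two-way layout (no checks) with known components."""
    rng = np.random.default_rng(seed)
    gv = rng.normal(0, np.sqrt(s2g), n_geno)
    gev = rng.normal(0, np.sqrt(s2ge), (n_geno, n_env))
    rows = [
        (f"G{i:03d}", f"E{e}", f"R{r}", False, "",
         mu + gv[i] + gev[i, e] + rng.normal(0, np.sqrt(s2e)))
        for i in range(n_geno) for e in range(n_env) for r in range(n_rep)
    ]
    return TrialTable(pd.DataFrame(
        rows, columns=["entry_id", "environment_id", "block_id",
                       "is_check", "check_id", "value"]))


def augmented_trial(n_entries=40, n_env=2, n_blocks=4, seed=3, s2g=1.0,
                    s2ge=0.3, s2e=0.5, block_sd=0.5, mu=5.0,
                    checks=("CHK1", "CHK2")) -> tuple[TrialTable, pd.Series]:
    """Augmented design: replicated checks, un-replicated entries.

    Returns (trial, true entry genetic values)."""
    rng = np.random.default_rng(seed)
    gv = pd.Series(rng.normal(0, np.sqrt(s2g), n_entries),
                   index=[f"G{i:03d}" for i in range(n_entries)])
    cv = {c: rng.normal(0, np.sqrt(s2g)) for c in checks}
    rows = []
    for e in range(n_env):
        env = f"E{e}"
        order = rng.permutation(n_entries)
        blocks = np.array_split(order, n_blocks)
        ge = rng.normal(0, np.sqrt(s2ge), n_entries)
        bef = rng.normal(0, block_sd, n_blocks)
        for b, idxs in enumerate(blocks):
            blk = f"B{b}"
            for i in idxs:
                rows.append((gv.index[i], env, blk, False, "",
                             mu + gv.iloc[i] + ge[i] + bef[b]
                             + rng.normal(0, np.sqrt(s2e))))
            for c in checks:
                rows.append((f"{c}@{env}:{blk}", env, blk, True, c,
                             mu + cv[c] + bef[b] + rng.normal(0, np.sqrt(s2e))))
    trial = TrialTable(pd.DataFrame(
        rows, columns=["entry_id", "environment_id", "block_id",
                       "is_check", "check_id", "value"]))
    return trial, gv
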