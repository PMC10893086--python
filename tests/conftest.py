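import numpy as np
import pandas as pd
import pytest

from chemomix import AnalyteTable, SampleMeta, SyntheticConfig, generate_study


def make_samples(
    n_per_group: int = 3,
    n_blanks: int = 0,
    cell_density: float = 1.0e5,
    dry_mass: float = 0.01,
    aliquot_volume: float = 50.0,
    technical_reps: int | None = None,
):
    """Biological samples named {treatment}-{rep} (plus optional blanks
    and technical duplicates {treatment}-{rep}.t{d})."""
    samples = []
    for treatment in ("control", "heat"):
        for rep in range(1, n_per_group + 1):
            base = SampleMeta(
                sample_id=f"{treatment}-{rep}",
                treatment=treatment,
                biological_replicate=rep,
                cell_density=cell_density,
                aliquot_volume=aliquot_volume,
                dry_mass=dry_mass,
            )
            if technical_reps is None:
                samples.append(base)
            else:
                from dataclasses import replace

                for d in range(1, technical_reps + 1):
                    samples.append(
                        replace(
                            base,
                            sample_id=f"{base.sample_id}.t{d}",
                            technical_replicate=d,
                        )
                    )
    for b in range(1, n_blanks + 1):
        samples.append(
            SampleMeta(
                sample_id=f"blank-{b}",
                treatment=None,
                biological_replicate=None,
                is_blank=True,
            )
        )
    return samples


def make_table(values, samples, layer="metabolite", analytes=None, classes=None):
    """AnalyteTable from a 2-D array (NaN entries become non-detects)."""
    values = np.asarray(values, dtype=float)
    analytes = analytes or [f"a{i + 1}" for i in range(values.shape[0])]
    ab = pd.DataFrame(values, index=analytes, columns=[s.sample_id for s in samples])
    cls = pd.Series(classes, index=analytes) if classes is not None else None
    return AnalyteTable(
        layer=layer,
        abundance=ab,
        detected=ab.notna(),
        samples=list(samples),
        analyte_class=cls,
    )


@pytest.fixture(scope="session")
def default_study():
    """One full-size synthetic study shared by read-only tests."""
    return generate_study(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A fast small-scale configuration for repeated simulation."""
    return dict(
        n_elements=4,
        n_metabolites=30,
        n_volatiles=40,
        n_unique_heat=10,
        n_unique_control=4,
        cluster_spec=(4, 2),
        contaminant_fraction=0.1,
    )


def null_config(n_metabolites=40):
    """A configuration with no planted structure at all."""
    return dict(
        n_elements=3,
        n_metabolites=n_metabolites,
        n_volatiles=4,
        effect_fraction=0.0,
        cluster_spec=(),
        n_unique_heat=0,
        n_unique_control=0,
        contaminant_fraction=0.0,
        plant_stoichiometry=False,
    )
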