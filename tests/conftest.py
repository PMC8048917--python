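import numpy as np
import pandas as pd
import pytest

from mrcoloc.sumstats import SummaryStatRecord, SummaryStatsTable


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.05,
    pvalue=0.045,
    n=10000,
    trait_type="quantitative",
):
    return SummaryStatRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        trait_type=trait_type,
    )


def make_table(records, trait_name="trait", trait_type="quantitative", **kw):
    return SummaryStatsTable.from_records(records, trait_name, trait_type, **kw)


def random_table(rng, n=10, trait_name="trait", prefix="rs"):
    """A well-formed random table; p-values consistent with beta/se."""
    from scipy import stats

    records = []
    for i in range(n):
        beta = rng.normal(0, 0.1)
        se = rng.uniform(0.02, 0.1)
        records.append(
            make_record(
                variant_id=f"{prefix}{i}",
                pos=1000 + 500 * i,
                eaf=rng.uniform(0.05, 0.95),
                beta=beta,
                se=se,
                pvalue=float(2 * stats.norm.sf(abs(beta / se))) or 1e-300,
            )
        )
    return make_table(records, trait_name=trait_name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tsv_writer(tmp_path):
    def _write(rows, name="sumstats.tsv",
               header=("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
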