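"""Full-scale synthetic benchmark on a genome-scale model.

Runs the complete simulation protocol — uniform fluxome sampling, synthetic
transcriptomes at eleven lambda levels (0.0 ... 1.0), entropy-method and
FBA+min-l2 predictions, Pearson scoring at carbon-core and genome scale —
against a locally provided genome-scale model such as the E. coli iJO1366
reconstruction (SBML or JSON).  Model files are not bundled; download one
from BiGG (http://bigg.ucsd.edu/models/iJO1366) and pass its path.

The seed is pinned so a given model file always reproduces the same table:

    python scripts/genome_scale_benchmark.py iJO1366.json --out sweep.tsv

Expect hours of CPU time at the published scale (11 x 1000 samples); use
--n to scale down.
"""

import argparse

DEFAULT_SEED = 1366
DEFAULT_LAMBDAS = [round(0.1 * i, 1) for i in range(11)]
DEFAULT_N = 1000
DEFAULT_THINNING = 100


def run(model_path: str, out_path: str, n: int = DEFAULT_N,
        seed: int = DEFAULT_SEED, thinning: int = DEFAULT_THINNING,
        methods=("pheflux", "fba_min_l2")):
    import entroflux as ef

    network = ef.load_model(model_path)
    table = ef.run_lambda_sweep(network, DEFAULT_LAMBDAS, n,
                                methods=list(methods), seed=seed,
                                thinning=thinning)
    table.to_csv(out_path, sep="\t", index=False)
    return table


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("model", help="genome-scale model file (SBML or JSON)")
    ap.add_argument("--out", default="genome_scale_sweep.tsv")
    ap.add_argument("--n", type=int, default=DEFAULT_N,
                    help="samples per lambda level")
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--thinning", type=int, default=DEFAULT_THINNING)
    args = ap.parse_args(argv)
    table = run(args.model, args.out, n=args.n, seed=args.seed,
                thinning=args.thinning)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
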