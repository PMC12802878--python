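2026-09-30 23:07:25,879 INFO proteasim: version 0.1.0
2026-09-30 23:07:25,879 INFO proteasim: config examples/config.yaml (hash 6e8ca14f9129f2bf)
2026-09-30 23:07:25,879 INFO proteasim: master seed 11
2026-09-30 23:07:26,121 INFO proteasim.digestion: trypsin: 24591 peptide rows after filtering
2026-09-30 23:07:26,188 INFO proteasim.digestion: lys-c: 8820 peptide rows after filtering
2026-09-30 23:07:26,322 INFO proteasim.digestion: lysarginase: 26334 peptide rows after filtering
2026-09-30 23:07:27,118 INFO proteasim: wrote demo/out/protease_scores.tsv and demo/out/protease_scores_summary.tsv
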