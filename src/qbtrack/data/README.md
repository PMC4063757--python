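# Termination-table fixtures

Subject x VOI binary matrices for the anterior (frontal-lobe) and posterior
(temporal/parietal/occipital) termination profiles of the q-ball-dissected
inferior fronto-occipital fasciculus in 20 healthy subjects, one file per
hemisphere and lobe group.  The `Y` column records that the bundle was
identified in the subject (all ones).  A cell value `1*` marks terminations
supported by very few streamlines; they count as indicator 1, with the flag
preserved so stricter thresholds can be applied post hoc.

The final `% of 1` row is the published per-VOI percentage summary and is
used as an independent audit of the transcription: the loader recomputes the
column percentages from the 20 subject rows and refuses to load if any entry
disagrees with this row.  File integrity is additionally guarded by sha256
checksums (`checksums.txt`).

Known source discrepancy: the narrative text states the left-hemisphere
cuneus at 30% in one place and 35% in another; the tables (and these
fixtures) give 35%.
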