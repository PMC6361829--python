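# Track-export dialect

One UTF-8 text file per arena/subject, tab-separated. Three sections, in
order: metadata lines, one column-header row, data rows.

## Metadata

Lines of the form `#key<TAB>value`. Required keys:

| key              | meaning                                                   |
|------------------|-----------------------------------------------------------|
| `arena_id`       | arena identifier (e.g. `A07`)                             |
| `trial_id`       | trial identifier (e.g. `T3`)                              |
| `sample_rate_hz` | nominal sample rate, samples/s (typically `3.33`)         |
| `genotype`       | `A$B` — genotype of the leaf disc in zone 1 (`A`) and zone 2 (`B`), separated by a `$` |

Optional keys: `leaf_position` (`p1$p2`, leaf positions per zone), `seed`
(for simulated tracks), and any other `#key<TAB>value` pair, which is
preserved verbatim on round trip.

## Columns

Header row (exact): `t_s  x_mm  y_mm  v_mm_s  zone  detected`

| column     | unit | notes                                                  |
|------------|------|--------------------------------------------------------|
| `t_s`      | s    | time since trial start; strictly increasing            |
| `x_mm`     | mm   | position, `-` when not detected                        |
| `y_mm`     | mm   | position, `-` when not detected                        |
| `v_mm_s`   | mm/s | instantaneous velocity; `-` when absent                |
| `zone`     |      | `1`, `2` (leaf zones), `3` (neutral), `-` when not detected |
| `detected` |      | `1` = tracking fix, `0` = not detected                 |

Missing fields are written as `-`. A row with `detected = 0` carries `-` for
position, velocity and zone.

## Reader normalisation

* Rows with non-numeric positions are treated as not detected.
* Missing rows (timestamp jumps larger than 1.5 sample intervals) are
  materialised as not-detected samples on the nominal time grid, so dropout
  has a single in-memory representation whether the exporter wrote sentinel
  rows or skipped rows.
* With `px_per_mm` given (20 px/mm for the standard camera setup), `x`, `y`
  and `v` are divided by it on read; all internal units are mm and seconds.

## Example

```
#arena_id	A01
#trial_id	T1
#sample_rate_hz	3.33
#genotype	Cur-3$Rmx-A180
t_s	x_mm	y_mm	v_mm_s	zone	detected
0.000000	10.98	0	0.012	3	1
0.300300	10.99	0	0.033	3	1
0.600601	-	-	-	-	0
0.900901	11.32	0	0.31	3	1
```
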