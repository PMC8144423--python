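# SYNTHETIC CFD mismatch penalties (deterministic heuristic stand-in;
# not the published table -- supply real values via the same TSV layout).
position	guide_base	target_base	penalty
1	A	C	0.522
1	A	G	0.95
1	A	T	0.522
1	C	A	0.522
1	C	G	0.522
1	C	T	0.95
1	G	A	0.95
1	G	C	0.522
1	G	T	0.522
1	T	A	0.522
1	T	C	0.95
1	T	G	0.522
2	A	C	0.502
2	A	G	0.913
2	A	T	0.502
2	C	A	0.502
2	C	G	0.502
2	C	T	0.913
2	G	A	0.913
2	G	C	0.502
2	G	T	0.502
2	T	A	0.502
2	T	C	0.913
2	T	G	0.502
3	A	C	0.482
3	A	G	0.876
3	A	T	0.482
3	C	A	0.482
3	C	G	0.482
3	C	T	0.876
3	G	A	0.876
3	G	C	0.482
3	G	T	0.482
3	T	A	0.482
3	T	C	0.876
3	T	G	0.482
4	A	C	0.462
4	A	G	0.839
4	A	T	0.462
4	C	A	0.462
4	C	G	0.462
4	C	T	0.839
4	G	A	0.839
4	G	C	0.462
4	G	T	0.462
4	T	A	0.462
4	T	C	0.839
4	T	G	0.462
5	A	C	0.441
5	A	G	0.803
5	A	T	0.441
5	C	A	0.441
5	C	G	0.441
5	C	T	0.803
5	G	A	0.803
5	G	C	0.441
5	G	T	0.441
5	T	A	0.441
5	T	C	0.803
5	T	G	0.441
6	A	C	0.421
6	A	G	0.766
6	A	T	0.421
6	C	A	0.421
6	C	G	0.421
6	C	T	0.766
6	G	A	0.766
6	G	C	0.421
6	G	T	0.421
6	T	A	0.421
6	T	C	0.766
6	T	G	0.421
7	A	C	0.401
7	A	G	0.729
7	A	T	0.401
7	C	A	0.401
7	C	G	0.401
7	C	T	0.729
7	G	A	0.729
7	G	C	0.401
7	G	T	0.401
7	T	A	0.401
7	T	C	0.729
7	T	G	0.401
8	A	C	0.381
8	A	G	0.692
8	A	T	0.381
8	C	A	0.381
8	C	G	0.381
8	C	T	0.692
8	G	A	0.692
8	G	C	0.381
8	G	T	0.381
8	T	A	0.381
8	T	C	0.692
8	T	G	0.381
9	A	C	0.36
9	A	G	0.655
9	A	T	0.36
9	C	A	0.36
9	C	G	0.36
9	C	T	0.655
9	G	A	0.655
9	G	C	0.36
9	G	T	0.36
9	T	A	0.36
9	T	C	0.655
9	T	G	0.36
10	A	C	0.34
10	A	G	0.618
10	A	T	0.34
10	C	A	0.34
10	C	G	0.34
10	C	T	0.618
10	G	A	0.618
10	G	C	0.34
10	G	T	0.34
10	T	A	0.34
10	T	C	0.618
10	T	G	0.34
11	A	C	0.32
11	A	G	0.582
11	A	T	0.32
11	C	A	0.32
11	C	G	0.32
11	C	T	0.582
11	G	A	0.582
11	G	C	0.32
11	G	T	0.32
11	T	A	0.32
11	T	C	0.582
11	T	G	0.32
12	A	C	0.3
12	A	G	0.545
12	A	T	0.3
12	C	A	0.3
12	C	G	0.3
12	C	T	0.545
12	G	A	0.545
12	G	C	0.3
12	G	T	0.3
12	T	A	0.3
12	T	C	0.545
12	T	G	0.3
13	A	C	0.279
13	A	G	0.508
13	A	T	0.279
13	C	A	0.279
13	C	G	0.279
13	C	T	0.508
13	G	A	0.508
13	G	C	0.279
13	G	T	0.279
13	T	A	0.279
13	T	C	0.508
13	T	G	0.279
14	A	C	0.259
14	A	G	0.471
14	A	T	0.259
14	C	A	0.259
14	C	G	0.259
14	C	T	0.471
14	G	A	0.471
14	G	C	0.259
14	G	T	0.259
14	T	A	0.259
14	T	C	0.471
14	T	G	0.259
15	A	C	0.239
15	A	G	0.434
15	A	T	0.239
15	C	A	0.239
15	C	G	0.239
15	C	T	0.434
15	G	A	0.434
15	G	C	0.239
15	G	T	0.239
15	T	A	0.239
15	T	C	0.434
15	T	G	0.239
16	A	C	0.219
16	A	G	0.397
16	A	T	0.219
16	C	A	0.219
16	C	G	0.219
16	C	T	0.397
16	G	A	0.397
16	G	C	0.219
16	G	T	0.219
16	T	A	0.219
16	T	C	0.397
16	T	G	0.219
17	A	C	0.198
17	A	G	0.361
17	A	T	0.198
17	C	A	0.198
17	C	G	0.198
17	C	T	0.361
17	G	A	0.361
17	G	C	0.198
17	G	T	0.198
17	T	A	0.198
17	T	C	0.361
17	T	G	0.198
18	A	C	0.178
18	A	G	0.324
18	A	T	0.178
18	C	A	0.178
18	C	G	0.178
18	C	T	0.324
18	G	A	0.324
18	G	C	0.178
18	G	T	0.178
18	T	A	0.178
18	T	C	0.324
18	T	G	0.178
19	A	C	0.158
19	A	G	0.287
19	A	T	0.158
19	C	A	0.158
19	C	G	0.158
19	C	T	0.287
19	G	A	0.287
19	G	C	0.158
19	G	T	0.158
19	T	A	0.158
19	T	C	0.287
19	T	G	0.158
20	A	C	0.138
20	A	G	0.25
20	A	T	0.138
20	C	A	0.138
20	C	G	0.138
20	C	T	0.25
20	G	A	0.25
20	G	C	0.138
20	G	T	0.138
20	T	A	0.138
20	T	C	0.25
20	T	G	0.138
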