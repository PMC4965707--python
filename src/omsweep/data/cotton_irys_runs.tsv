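date_run	quantity_mbp	molecule_n50_kbp	labels_per_100kbp
28-May-14	5861.00	218.6	7.2
04-Jun-14	15723.90	154.5	8.2
05-Jun-14	32131.70	150.4	8.6
05-Jun-14	18135.40	143.9	9.0
22-Jul-14	7122.50	188.7	6.1
23-Jul-14	9651.20	175.8	9.3
24-Jul-14	2833.90	165.8	9.1
24-Jul-14	5492.80	198.6	10.2
25-Jul-14	15037.10	189.7	6.1
28-Jul-14	6246.70	189.7	6.6
29-Jul-14	4848.80	155.4	10.0
30-Jul-14	9029.30	163.8	10.1
31-Jul-14	15970.40	168.3	10.1
05-Aug-14	12213.10	171.2	10.3
06-Aug-14	15718.60	169.8	10.2
07-Aug-14	7312.50	161.5	10.6
07-Aug-14	1176.00	155.5	11.3
07-Aug-14	17104.90	160.0	10.9
07-Aug-14	15670.10	150.6	11.0
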