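E	D	M	cas_pair	raw_score	final_score	category	reliability	check_reason
4	0	0	agree	4.0	4.0	Maintain	high	none
3	0	1	agree	3.0	3.0	Maintain	medium	none
3	0	1	incomparable	3.0	3.0	Maintain	medium	none
3	1	0	agree	2.8	2.8	Check	none	verify_name
3	1	0	disagree	2.8	0.0	Reject	none	none
2	0	2	agree	2.0	2.0	Check	none	verify_name
2	0	2	incomparable	2.0	2.0	Check	none	need_one_confirmation
2	0	2	incomparable	2.0	2.0	Check	none	verify_cas_and_need_one
2	1	1	agree	1.8	1.8	Check	none	verify_name
2	1	1	disagree	1.8	0.0	Reject	none	none
2	1	1	incomparable	1.8	1.8	Check	none	need_one_confirmation
2	2	0	agree	1.6	0.0	Reject	none	none
2	2	0	disagree	1.6	0.0	Reject	none	none
1	0	3	incomparable	1.0	1.0	Check	none	need_two_confirmations
0	0	4	incomparable	0.0	0.0	Reject	none	none
0	2	2	disagree	-0.4	0.0	Reject	none	none
0	2	2	incomparable	-0.4	0.0	Reject	none	none
0	3	1	disagree	-0.6	0.0	Reject	none	none
0	3	1	incomparable	-0.6	0.0	Reject	none	none
0	4	0	disagree	-0.8	0.0	Reject	none	none
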