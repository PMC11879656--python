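howl_no,timestamp,true_lat,true_lon,est_lat,est_lon,distance_m,recorder_sites,local_hull,group
1,2021-08-31T20:29:05,46.14972,21.18869,46.14945,21.18958,75,2;12;13;14,Inside,A
2,2021-08-31T20:30:11,46.14972,21.18869,46.15072,21.18907,115,12;13;14,Inside,A
3,2021-08-31T20:30:17,46.14972,21.18869,46.14927,21.18947,78,12;13;14,Inside,A
4,2021-09-02T22:38:35,46.14735,21.19503,46.14763,21.19471,40,11;12;13;14,Inside,B
5,2021-09-02T22:38:47,46.14735,21.19503,46.14723,21.19445,46,11;13;14,Outside,B
6,2021-09-02T22:38:51,46.14735,21.19503,46.14753,21.19487,24,11;12;13;14,Inside,B
7,2021-09-02T22:42:35,46.14735,21.19503,46.14745,21.19456,38,11;12;13;14,Inside,B
8,2021-09-02T22:42:43,46.14735,21.19503,46.14758,21.19485,29,11;12;13;14,Inside,B
9,2021-09-02T22:42:57,46.14735,21.19503,46.14738,21.19491,10,11;13;14,Outside,B
10,2021-09-02T22:57:41,46.14463,21.18173,46.14462,21.18175,2,11;13;14,Outside,C
11,2021-09-02T22:57:54,46.14463,21.18173,46.14473,21.18079,73,11;13;14,Outside,C
12,2021-09-02T22:57:59,46.14463,21.18173,46.14471,21.18139,28,11;13;14,Outside,C
13,2021-09-02T22:59:55,46.14463,21.18173,46.14476,21.18156,20,11;13;14,Outside,C
14,2021-09-02T23:00:02,46.14463,21.18173,46.14471,21.18139,28,11;13;14,Outside,C
15,2021-09-02T23:00:14,46.14463,21.18173,46.14483,21.18145,31,11;13;14,Outside,C
16,2021-09-02T23:02:06,46.14463,21.18173,46.14461,21.18152,16,11;13;14,Outside,C
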